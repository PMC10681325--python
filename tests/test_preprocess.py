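"""QC, normalisation, HVG selection and gene-activity counting."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scnetpas import preprocess
from scnetpas.preprocess import GeneAnnotation
from conftest import dense_matrix


class TestQCFilter:
    def test_cell_at_exactly_one_percent_removed(self):
        # 200 genes x 10 cells; one cell detects exactly 2 genes = 1% (not >1%)
        vals = np.ones((200, 10))
        vals[:, 0] = 0
        vals[0, 0] = vals[1, 0] = 1
        x = dense_matrix(vals)
        out, rep = preprocess.qc_filter(x)
        assert rep.cells_removed == 1 and out.n_cells == 9
        assert "c0" not in out.cells

    def test_dense_matrix_untouched(self):
        x = dense_matrix(np.ones((5, 4)))
        out, rep = preprocess.qc_filter(x)
        assert rep.cells_removed == 0 and rep.genes_removed == 0
        assert out.values.shape == (5, 4)

    def test_gene_in_quarter_of_cells_kept(self):
        vals = np.ones((5, 4))
        vals[0] = [3, 0, 0, 0]  # nonzero in 25% of cells > 1%
        out, _ = preprocess.qc_filter(dense_matrix(vals))
        assert "g0" in out.genes

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(0.3, size=(120, 50)).astype(float)
        vals[:, 0] = 0
        vals[0, 0] = 1  # cell detecting 1/120 genes < 1%? 0.83% -> removed
        x = dense_matrix(vals)
        once, _ = preprocess.qc_filter(x)
        twice, rep2 = preprocess.qc_filter(once)
        assert rep2.cells_removed == 0 and rep2.genes_removed == 0

    def test_everything_removed_is_hard_error(self):
        vals = np.zeros((100, 5))
        vals[0, :] = 1  # every cell detects 1% of genes exactly, not >1%
        with pytest.raises(ValueError, match="QC removed"):
            preprocess.qc_filter(dense_matrix(vals))


class TestLogNormalize:
    def test_hand_value(self):
        x = dense_matrix([[1], [3]])
        out = preprocess.log_normalize(x, scale=1e4)
        assert out.toarray()[0, 0] == pytest.approx(np.log1p(2500), rel=1e-12)
        assert out.layer_tag == "lognorm"

    def test_zero_count_stays_zero(self):
        out = preprocess.log_normalize(dense_matrix([[0, 1], [2, 3]]))
        assert out.toarray()[0, 0] == 0.0

    def test_scale_invariance_of_cell_column(self):
        a = preprocess.log_normalize(dense_matrix([[1], [4], [5]]))
        b = preprocess.log_normalize(dense_matrix([[10], [40], [50]]))
        assert np.allclose(a.toarray(), b.toarray())

    def test_preserves_within_cell_rank_order(self, rng):
        vals = rng.poisson(3, size=(30, 8)).astype(float) + rng.random((30, 8))
        out = preprocess.log_normalize(dense_matrix(vals)).toarray()
        for j in range(8):
            assert np.array_equal(np.argsort(vals[:, j]), np.argsort(out[:, j]))

    def test_zero_cell_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            preprocess.log_normalize(dense_matrix([[1, 0], [2, 0]]))


class TestSelectHVG:
    def test_n_top_equals_m_identity(self):
        x = dense_matrix(np.arange(12.0).reshape(3, 4), layer="lognorm")
        out = preprocess.select_hvg(x, 3)
        assert out.genes == x.genes
        assert (out.values != x.values).nnz == 0

    def test_constant_gene_loses(self):
        vals = np.array([[1.0, 1.0, 1.0], [0.1, 2.0, 4.0]])
        out = preprocess.select_hvg(dense_matrix(vals, "lognorm"), 1)
        assert out.genes == ["g1"]

    def test_high_variance_block_selected(self, rng):
        base = rng.normal(0, 1, size=(50, 40))
        base[:10] *= 5  # 25x the variance
        out = preprocess.select_hvg(dense_matrix(np.abs(base), "lognorm"), 10)
        assert out.genes == [f"g{i}" for i in range(10)]

    def test_n_top_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            preprocess.select_hvg(dense_matrix(np.ones((2, 3)), "lognorm"), 5)


def _ann(rows):
    return GeneAnnotation(
        pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "start", "end", "strand"])
    )


class TestGeneActivity:
    def test_strand_aware_upstream_windows(self):
        ann = _ann({"gp": ("chr1", 5000, 6000, "+"), "gm": ("chr2", 5000, 6000, "-")})
        frags = pd.DataFrame(
            [
                ("chr1", 3500, 4200, "c1"),   # in + upstream [3000, 4999]
                ("chr2", 6500, 7200, "c1"),   # in - upstream [6001, 8000]
                ("chr1", 100, 200, "c1"),     # outside every region
                ("chr2", 3500, 4200, "c1"),   # - strand has NO upstream there
            ],
            columns=["chrom", "start", "end", "barcode"],
        )
        act = preprocess.gene_activity(frags, ann, ["c1"])
        assert act.toarray().tolist() == [[1], [1]]
        assert act.layer_tag == "gene_activity"

    def test_one_bp_overlap_counts(self):
        ann = _ann({"g": ("chr1", 5000, 6000, "+")})
        frags = pd.DataFrame([("chr1", 2500, 3000, "c1")], columns=["chrom", "start", "end", "barcode"])
        act = preprocess.gene_activity(frags, ann, ["c1"])
        assert act.toarray()[0, 0] == 1  # touches upstream start 3000 by 1 bp

    def test_fragment_counts_once_per_overlapping_gene(self):
        ann = _ann({"a": ("chr1", 100, 500, "+"), "b": ("chr1", 400, 900, "+")})
        frags = pd.DataFrame([("chr1", 420, 480, "c1")], columns=["chrom", "start", "end", "barcode"])
        act = preprocess.gene_activity(frags, ann, ["c1"], upstream=0)
        assert act.toarray().ravel().tolist() == [1, 1]

    def test_unknown_chromosome_skipped_with_warning(self):
        ann = _ann({"g": ("chr1", 100, 500, "+")})
        frags = pd.DataFrame([("chrUn", 100, 200, "c1")], columns=["chrom", "start", "end", "barcode"])
        with pytest.warns(UserWarning, match="skipped"):
            act = preprocess.gene_activity(frags, ann, ["c1"])
        assert act.values.nnz == 0


def test_read_fragments_converts_bed_to_inclusive(tmp_path):
    p = tmp_path / "frags.bed"
    p.write_text("chr1\t99\t200\tc1\nchr1\t0\t10\tc2\n")
    df = preprocess.read_fragments(p)
    assert df["start"].tolist() == [100, 1]
    assert df["end"].tolist() == [200, 10]


def test_read_gtf(tmp_path):
    p = tmp_path / "g.gtf"
    p.write_text(
        "# comment\n"
        'chr1\tsrc\tgene\t500\t900\t.\t+\t.\tgene_id "gA"; gene_name "A";\n'
        'chr1\tsrc\texon\t500\t600\t.\t+\t.\tgene_id "gA";\n'
        'chr2\tsrc\tgene\t100\t300\t.\t-\t.\tgene_id "gB";\n'
    )
    ann = preprocess.read_gtf(p)
    assert list(ann.table.index) == ["gA", "gB"]
    assert ann.table.loc["gB", "strand"] == "-"
    ext = ann.extended_regions(2000)
    assert ext.loc["gA", "start"] == 1  # clipped at chromosome start
    assert ext.loc["gB", "end"] == 2300
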