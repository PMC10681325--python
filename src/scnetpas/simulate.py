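"""Synthetic single-cell data generation for testing and demonstration.

Counts follow a negative-binomial base (single-cell counts are
overdispersed relative to Poisson); each phenotype designates blocks of
"active" genes whose mean is elevated by a fold factor in cells of that
phenotype.  Dropout thins nonzero entries at a configurable rate, and
Gaussian perturbation (clipped at zero) mimics additive measurement
noise.  A fragment simulator places ATAC-style intervals inside or
outside extended gene regions so the gene-activity counter can be
validated against a known truth matrix.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import GeneAnnotation
from .types import GeneCellMatrix, PhenotypeTable

__all__ = [
    "SimSpec",
    "simulate_expression",
    "add_dropout",
    "add_gaussian",
    "simulate_fragments",
    "toy_annotation",
]


@dataclass
class SimSpec:
    m: int = 200
    n: int = 150
    n_phenotypes: int = 3
    block_size: int = 10
    active_fold: float = 5.0
    dropout: float = 0.2
    base_mean: float = 2.0
    dispersion: float = 0.5  # NB size parameter; smaller = more overdispersed
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")
        if self.n_phenotypes * self.block_size > self.m:
            raise ValueError("active blocks exceed the gene count")
        if self.n < self.n_phenotypes:
            raise ValueError("need at least one cell per phenotype")


def _nb_counts(rng, mean, size_param, shape):
    # negative binomial with mean `mean` and size (dispersion) `size_param`
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def simulate_expression(spec: SimSpec) -> tuple[GeneCellMatrix, PhenotypeTable, dict[str, list[str]]]:
    """Simulate counts with phenotype-specific active gene blocks.

    Returns the count matrix, the phenotype table, and the truth map
    phenotype -> active gene list.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(spec.m)]
    cells = [f"c{j:04d}" for j in range(spec.n)]
    pheno_of = np.array([j % spec.n_phenotypes for j in range(spec.n)])
    labels = [f"pheno{k}" for k in range(spec.n_phenotypes)]
    # per-gene baseline means, lognormal around base_mean
    base = spec.base_mean * rng.lognormal(0.0, 0.3, size=spec.m)
    mean_matrix = np.tile(base[:, None], (1, spec.n))
    truth: dict[str, list[str]] = {}
    for k in range(spec.n_phenotypes):
        lo, hi = k * spec.block_size, (k + 1) * spec.block_size
        truth[labels[k]] = genes[lo:hi]
        mean_matrix[lo:hi][:, pheno_of == k] *= spec.active_fold
    counts = _nb_counts(rng, mean_matrix, spec.dispersion, (spec.m, spec.n)).astype(float)
    if spec.dropout > 0:
        keep = rng.random(counts.shape) >= spec.dropout
        counts = np.where(counts > 0, counts * keep, counts)
    x = GeneCellMatrix(sp.csr_matrix(counts), genes, cells, "counts")
    phen = PhenotypeTable({c: labels[pheno_of[j]] for j, c in enumerate(cells)})
    return x, phen, truth


def add_dropout(x: GeneCellMatrix, rate: float, seed: int = 0) -> GeneCellMatrix:
    """Zero each nonzero entry independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = x.values.copy()
    if rate > 0 and out.nnz:
        keep = rng.random(out.nnz) >= rate
        out.data = out.data * keep
        out.eliminate_zeros()
    return GeneCellMatrix(out, list(x.genes), list(x.cells), x.layer_tag)


def add_gaussian(x: GeneCellMatrix, sd: float, seed: int = 0) -> GeneCellMatrix:
    """Add i.i.d. N(0, sd^2) noise to every entry, clipping at zero."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    dense = x.toarray() + rng.normal(0.0, sd, size=x.values.shape)
    return GeneCellMatrix(sp.csr_matrix(np.clip(dense, 0.0, None)), list(x.genes), list(x.cells), x.layer_tag)


def toy_annotation(n_genes: int, gene_length: int = 1000, gap: int = 10_000, chrom: str = "chr1") -> GeneAnnotation:
    """Non-overlapping equally spaced genes on one chromosome, alternating strand.

    Gaps are wide enough that 2-kb upstream extensions never collide.
    """
    rows = {}
    pos = 50_000
    for i in range(n_genes):
        rows[f"g{i:04d}"] = (chrom, pos, pos + gene_length - 1, "+" if i % 2 == 0 else "-")
        pos += gap
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "start", "end", "strand"])
    return GeneAnnotation(df)


def simulate_fragments(
    counts: np.ndarray,
    ann: GeneAnnotation,
    cells: list[str],
    n_intergenic: int = 0,
    upstream: int = 2000,
    fragment_length: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Place fragments inside extended gene regions to match a truth matrix.

    ``counts[g, c]`` fragments are placed fully inside gene g's extended
    region for cell c; ``n_intergenic`` extra fragments per cell land far
    from every gene.  With non-overlapping genes,
    :func:`scnetpas.preprocess.gene_activity` recovers ``counts`` exactly.
    Returns a 1-based inclusive fragment table (chrom, start, end, barcode).
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts)
    regions = ann.extended_regions(upstream)
    if counts.shape != (len(regions), len(cells)):
        raise ValueError("counts shape must be (n_genes, n_cells)")
    rows = []
    for gi, (chrom, start, end) in enumerate(zip(regions["chrom"], regions["start"], regions["end"])):
        span = int(end) - int(start) + 1 - fragment_length
        for cj, cell in enumerate(cells):
            for _ in range(int(counts[gi, cj])):
                offset = int(rng.integers(0, max(span, 1)))
                fs = int(start) + offset
                rows.append((chrom, fs, fs + fragment_length - 1, cell))
    far = int(regions["end"].max()) + 10 * upstream
    for cell in cells:
        for _ in range(n_intergenic):
            fs = far + int(rng.integers(0, 10_000))
            rows.append((regions["chrom"].iloc[0], fs, fs + fragment_length - 1, cell))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"])
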