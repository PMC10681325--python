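"""Quality control, normalisation, HVG selection and scATAC gene activity.

QC keeps cells whose fraction of detected genes exceeds ``cell_frac`` and
genes detected in more than ``gene_frac`` of cells (strict inequalities),
with fractions computed against the pre-filter dimensions and the cell
filter applied first.  Normalisation is the global-scaling LogNormalize:
ln(1 + count / cell_total * scale).  Gene activity counts ATAC fragments
overlapping the gene body plus a strand-aware 2-kb upstream window.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import GeneCellMatrix

__all__ = [
    "QCReport",
    "GeneAnnotation",
    "qc_filter",
    "log_normalize",
    "select_hvg",
    "gene_activity",
    "read_gtf",
    "read_fragments",
]


@dataclass
class QCReport:
    cells_kept: int
    cells_removed: int
    genes_kept: int
    genes_removed: int
    cell_frac: float
    gene_frac: float

    def __post_init__(self) -> None:
        assert self.cells_kept + self.cells_removed >= 0
        assert self.genes_kept + self.genes_removed >= 0


@dataclass
class GeneAnnotation:
    """Per-gene genomic intervals, 1-based inclusive coordinates."""

    table: pd.DataFrame  # index: gene id; columns: chrom, start, end, strand

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "strand"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"annotation missing columns {sorted(need - set(self.table.columns))}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("annotation has start > end")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")

    def extended_regions(self, upstream: int = 2000) -> pd.DataFrame:
        """Gene body plus strand-aware upstream window, clipped at 1."""
        t = self.table
        plus = t["strand"] == "+"
        start = np.where(plus, t["start"] - upstream, t["start"])
        end = np.where(plus, t["end"], t["end"] + upstream)
        return pd.DataFrame(
            {"chrom": t["chrom"].to_numpy(), "start": np.maximum(start, 1), "end": end},
            index=t.index,
        )


def qc_filter(
    x: GeneCellMatrix, cell_frac: float = 0.01, gene_frac: float = 0.01
) -> tuple[GeneCellMatrix, QCReport]:
    """Remove low-quality cells, then low-prevalence genes.

    A cell is kept iff its detected-gene fraction (against the pre-filter
    gene count) is strictly greater than ``cell_frac``; a gene is kept iff
    it is nonzero in strictly more than ``gene_frac`` of the pre-filter
    cells.  Raises if either axis empties, with the report attached.
    """
    m, n = x.values.shape
    nz = x.values.copy()
    nz.data = np.ones_like(nz.data)
    genes_per_cell = np.asarray(nz.sum(axis=0)).ravel()
    cell_mask = genes_per_cell / m > cell_frac
    sub = x.values[:, cell_mask]
    nz2 = sub.copy()
    nz2.data = np.ones_like(nz2.data)
    cells_per_gene = np.asarray(nz2.sum(axis=1)).ravel()
    gene_mask = cells_per_gene / n > gene_frac
    report = QCReport(
        cells_kept=int(cell_mask.sum()),
        cells_removed=int(n - cell_mask.sum()),
        genes_kept=int(gene_mask.sum()),
        genes_removed=int(m - gene_mask.sum()),
        cell_frac=cell_frac,
        gene_frac=gene_frac,
    )
    if report.cells_kept == 0 or report.genes_kept == 0:
        raise ValueError(f"QC removed an entire axis: {report}")
    out = GeneCellMatrix(
        sub[gene_mask],
        [g for g, keep in zip(x.genes, gene_mask) if keep],
        [c for c, keep in zip(x.cells, cell_mask) if keep],
        x.layer_tag,
    )
    return out, report


def log_normalize(x: GeneCellMatrix, scale: float = 1e4) -> GeneCellMatrix:
    """Global-scaling normalisation: value <- ln(1 + count/cell_total * scale)."""
    totals = np.asarray(x.values.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("cannot normalise: all-zero cell column present")
    out = x.values.tocsc(copy=True).astype(float)
    for j in range(out.shape[1]):
        sl = slice(out.indptr[j], out.indptr[j + 1])
        out.data[sl] = np.log1p(out.data[sl] / totals[j] * scale)
    return GeneCellMatrix(out.tocsr(), list(x.genes), list(x.cells), "lognorm")


def select_hvg(x: GeneCellMatrix, n_top: int) -> GeneCellMatrix:
    """Keep the ``n_top`` genes with highest variance-stabilised dispersion.

    Genes are ranked by the variance of their centred values clipped at
    +/- sqrt(n) — unit expected variance standing in for a fitted
    mean-variance trend.  Ties break toward earlier gene order, and the
    retained genes keep their input order.
    """
    if x.layer_tag == "counts":
        raise ValueError("select_hvg expects a lognorm or gene_activity layer")
    m, n = x.values.shape
    if n_top > m:
        raise ValueError(f"n_top={n_top} exceeds gene count {m}")
    if n_top == m:
        return x.copy()
    dense = x.toarray()
    mu = dense.mean(axis=1, keepdims=True)
    z = np.clip(dense - mu, -np.sqrt(n), np.sqrt(n))
    score = z.var(axis=1, ddof=1)
    # stable sort on negated score keeps input order among ties
    order = np.argsort(-score, kind="stable")[:n_top]
    keep = np.zeros(m, dtype=bool)
    keep[order] = True
    return GeneCellMatrix(
        x.values[keep],
        [g for g, k in zip(x.genes, keep) if k],
        list(x.cells),
        x.layer_tag,
    )


def read_gtf(path: str | os.PathLike) -> GeneAnnotation:
    """Read gene records from a GTF file (chrom, start, end, strand, gene_id)."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = f[8]
            gid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gid = part.split(" ", 1)[1].strip().strip('"')
                    break
            if gid is None:
                continue
            rows[gid] = (f[0], int(f[3]), int(f[4]), f[6])
    if not rows:
        raise ValueError(f"{path}: no gene records found")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "start", "end", "strand"])
    return GeneAnnotation(df)


def read_fragments(path: str | os.PathLike) -> pd.DataFrame:
    """Read a fragments BED file (chrom, start, end, barcode).

    BED half-open 0-based intervals are converted to 1-based inclusive.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "barcode"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "start": int, "end": int, "barcode": str},
    )
    df["start"] = df["start"] + 1  # BED -> 1-based inclusive
    return df


def gene_activity(
    fragments: pd.DataFrame,
    ann: GeneAnnotation,
    cells: list[str],
    upstream: int = 2000,
) -> GeneCellMatrix:
    """Count, per gene and cell, fragments overlapping the extended gene region.

    A fragment overlapping two genes' regions counts once per gene; a
    fragment on a chromosome absent from the annotation is skipped with a
    counted warning.  ``fragments`` uses 1-based inclusive coordinates
    (see :func:`read_fragments`).
    """
    regions = ann.extended_regions(upstream)
    cell_idx = {c: j for j, c in enumerate(cells)}
    genes = list(regions.index)
    counts = sp.lil_matrix((len(genes), len(cells)))
    known_chroms = set(regions["chrom"])
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        by_chrom.setdefault(chrom, []).append((int(start), int(end), gi))
    skipped = 0
    for chrom, fstart, fend, bc in zip(
        fragments["chrom"], fragments["start"], fragments["end"], fragments["barcode"]
    ):
        if chrom not in known_chroms:
            skipped += 1
            continue
        j = cell_idx.get(bc)
        if j is None:
            continue
        for gstart, gend, gi in by_chrom[chrom]:
            if fstart <= gend and fend >= gstart:  # >=1 bp overlap, inclusive coords
                counts[gi, j] += 1
    if skipped:
        warnings.warn(f"{skipped} fragments on chromosomes absent from the annotation were skipped")
    return GeneCellMatrix(counts.tocsr(), genes, list(cells), "gene_activity")
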