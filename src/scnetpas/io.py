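"""Readers and writers for the external formats the pipeline touches.

Supported dialects: Matrix Market directories (matrix.mtx + features.tsv +
barcodes.tsv), dense CSV/TSV gene x cell tables, GMT gene-set files,
phenotype label TSVs, score-matrix CSVs and network edge-list TSVs.
Matrix Market indices are 1-based on disk (per the standard) and 0-based
in memory; conversion happens only at this boundary via scipy.io.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import GeneCellMatrix, GeneSetCollection, GeneCellNetwork, PathwayScoreMatrix, PhenotypeTable

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "read_phenotypes",
    "write_phenotypes",
    "write_score_matrix",
    "read_score_matrix",
    "write_network",
    "read_network",
]

_MTX_NAMES = ("matrix.mtx", "features.tsv", "barcodes.tsv")


class FormatError(ValueError):
    """Raised when an on-disk file does not conform to its format."""


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_matrix(path: str | os.PathLike, format: str = "mtx_dir", layer_tag: str = "counts") -> GeneCellMatrix:
    """Read a gene x cell matrix from disk.

    ``mtx_dir`` expects a directory with matrix.mtx, features.tsv (genes)
    and barcodes.tsv (cells); CSV/TSV expect genes as rows, a leading
    gene-identifier column, and cell identifiers in the header.
    """
    path = Path(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FormatError(f"{path} is not a directory")
        missing = [n for n in _MTX_NAMES if not (path / n).exists()]
        if missing:
            raise FormatError(f"mtx_dir {path} missing companion file(s): {missing}")
        values = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        genes = _read_id_column(path / "features.tsv")
        cells = _read_id_column(path / "barcodes.tsv")
        if values.shape == (len(cells), len(genes)) and len(genes) != len(cells):
            values = values.T.tocsr()  # stored cells-as-rows; normalise orientation
        return GeneCellMatrix(values, genes, cells, layer_tag)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        return GeneCellMatrix(
            sp.csr_matrix(df.to_numpy(dtype=float)),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            layer_tag,
        )
    raise ValueError(f"unknown format {format!r}")


def write_matrix(x: GeneCellMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as an mtx_dir (matrix.mtx + features.tsv + barcodes.tsv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = x.values.tocoo()
    if x.layer_tag == "counts" and coo.nnz and np.allclose(coo.data, np.round(coo.data)):
        coo = coo.astype(int)
    scipy.io.mmwrite(path / "matrix.mtx", coo, precision=12)
    (path / "features.tsv").write_text("".join(g + "\n" for g in x.genes))
    (path / "barcodes.tsv").write_text("".join(c + "\n" for c in x.cells))


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: one gene set per line (name, description, genes...).

    Duplicate genes within a line are dropped with a warning; a line with
    fewer than three fields is a parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            name = fields[0]
            genes, seen = [], set()
            dup = False
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dup = True
                    continue
                seen.add(g)
                genes.append(g)
            if dup:
                warnings.warn(f"GMT line {lineno} ({name}): duplicate genes removed")
            if not genes:
                raise FormatError(f"GMT line {lineno} ({name}): no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source_tag=str(path))


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read a two-column TSV of cell identifier and phenotype label."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    return PhenotypeTable(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_phenotypes(phen: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for cell, label in phen.assignments.items():
            fh.write(f"{cell}\t{label}\n")


def write_score_matrix(scores: PathwayScoreMatrix, path: str | os.PathLike) -> None:
    """Write pathway x cell scores as CSV (pathway rows, cell columns)."""
    df = pd.DataFrame(scores.scores, index=scores.pathways, columns=scores.cells)
    df.to_csv(path, float_format="%.12g")


def read_score_matrix(path: str | os.PathLike) -> PathwayScoreMatrix:
    df = pd.read_csv(path, index_col=0)
    return PathwayScoreMatrix(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns])


def write_network(net: GeneCellNetwork, path: str | os.PathLike) -> None:
    """Write a gene-cell network as a TSV edge list.

    One row per undirected edge of the joint adjacency (upper triangle),
    with node_kind flags so a gene and a cell sharing an identifier string
    remain distinguishable.  Weights keep 12 significant digits.
    """
    names = net.node_names
    m = len(net.genes)
    kinds = ["gene"] * m + ["cell"] * len(net.cells)
    joint = sp.triu(_joint_adjacency(net), k=0).tocoo()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tsource_kind\ttarget_kind\n")
        for i, j, w in zip(joint.row, joint.col, joint.data):
            if i == j:
                continue  # diagonal never carries an association
            fh.write(f"{names[i]}\t{names[j]}\t{w:.12g}\t{kinds[i]}\t{kinds[j]}\n")


def _joint_adjacency(net: GeneCellNetwork) -> sp.csr_matrix:
    return sp.bmat([[net.G, net.K], [net.K.T, net.C]], format="csr")


def read_network(path: str | os.PathLike) -> GeneCellNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    from .assembly import assemble

    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    need = {"source", "target", "weight", "source_kind", "target_kind"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    genes: list[str] = []
    cells: list[str] = []
    for name, kind in zip(
        pd.concat([df["source"], df["target"]]),
        pd.concat([df["source_kind"], df["target_kind"]]),
    ):
        target = genes if kind == "gene" else cells
        if name not in target:
            target.append(name)
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: i for i, c in enumerate(cells)}
    m, n = len(genes), len(cells)
    G = sp.lil_matrix((m, m))
    C = sp.lil_matrix((n, n))
    K = sp.lil_matrix((m, n))
    for _, row in df.iterrows():
        sk, tk, w = row["source_kind"], row["target_kind"], float(row["weight"])
        if sk == "gene" and tk == "gene":
            i, j = gi[row["source"]], gi[row["target"]]
            G[i, j] = G[j, i] = w
        elif sk == "cell" and tk == "cell":
            i, j = ci[row["source"]], ci[row["target"]]
            C[i, j] = C[j, i] = w
        else:
            g, c = (row["source"], row["target"]) if sk == "gene" else (row["target"], row["source"])
            K[gi[g], ci[c]] = w
    return assemble(G.tocsr(), C.tocsr(), K.tocsr(), genes=genes, cells=cells, normalize_blocks=False)
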