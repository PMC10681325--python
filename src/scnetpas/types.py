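"""Core in-memory containers shared across the pipeline.

The canonical orientation everywhere in this package is genes-as-rows,
cells-as-columns.  Sparse values are stored as ``scipy.sparse.csr_matrix``;
dense blocks (embeddings, adjacency blocks of small networks) are plain
``numpy`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeneCellMatrix",
    "GeneSetCollection",
    "PhenotypeTable",
    "GeneCellNetwork",
    "PathwayScoreMatrix",
]

_VALID_LAYERS = ("counts", "lognorm", "gene_activity")


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")


@dataclass
class GeneCellMatrix:
    """A gene x cell matrix with identifiers and a layer tag.

    Parameters
    ----------
    values
        Nonnegative expression values, shape ``(m, n)`` with genes as rows.
        Any scipy-sparse or dense input is normalised to CSR.
    genes, cells
        Ordered unique identifiers for rows and columns.
    layer_tag
        One of ``counts``, ``lognorm``, ``gene_activity``.
    """

    values: sp.csr_matrix
    genes: list[str]
    cells: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        m, n = self.values.shape
        if m != len(self.genes) or n != len(self.cells):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.genes)} genes "
                f"x {len(self.cells)} cells"
            )
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one gene and one cell")
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        if self.layer_tag not in _VALID_LAYERS:
            raise ValueError(f"layer_tag must be one of {_VALID_LAYERS}")
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("matrix contains non-finite values")
        if self.layer_tag in ("counts", "gene_activity") and self.values.nnz:
            if self.values.data.min() < 0:
                raise ValueError(f"{self.layer_tag} layer contains negative values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def copy(self) -> "GeneCellMatrix":
        return GeneCellMatrix(
            self.values.copy(), list(self.genes), list(self.cells), self.layer_tag
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); every set non-empty, no within-set duplicates."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class PhenotypeTable:
    """Cell -> phenotype label assignments."""

    assignments: dict[str, str]

    def labels(self) -> list[str]:
        """Distinct phenotype labels in first-appearance order."""
        out: list[str] = []
        for v in self.assignments.values():
            if v not in out:
                out.append(v)
        return out

    def cells_of(self, label: str) -> list[str]:
        return [c for c, v in self.assignments.items() if v == label]

    def validate_against(self, matrix_cells) -> None:
        known = set(matrix_cells)
        missing = [c for c in self.assignments if c not in known]
        if missing:
            raise ValueError(
                f"{len(missing)} labeled cells absent from the matrix, e.g. {missing[:5]}"
            )


@dataclass
class GeneCellNetwork:
    """Block-assembled weighted network over gene and cell nodes.

    ``G`` (gene-gene), ``C`` (cell-cell) and ``K`` (gene-cell) are the
    min-max normalised blocks; ``W`` is the column-stochastic transition
    matrix over the joint node set, genes first then cells.
    """

    genes: list[str]
    cells: list[str]
    G: sp.csr_matrix
    C: sp.csr_matrix
    K: sp.csr_matrix
    W: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return len(self.genes) + len(self.cells)

    @property
    def node_names(self) -> list[str]:
        return list(self.genes) + list(self.cells)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cell_index(self) -> dict[str, int]:
        m = len(self.genes)
        return {c: m + j for j, c in enumerate(self.cells)}


@dataclass
class PathwayScoreMatrix:
    """Pathway x cell permutation-adjusted activity scores in [0, 1]."""

    scores: np.ndarray  # (n_pathways, n_cells)
    pathways: list[str]
    cells: list[str]
    seed_gene_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pathways), len(self.cells)):
            raise ValueError("score matrix shape does not match labels")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("pathway activity scores must lie in [0, 1]")
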