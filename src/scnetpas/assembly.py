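"""Block assembly of the gene-cell association network.

The refined gene-gene block G, refined cell-cell block C and the
autoencoder's gene-cell association block K are each min-max normalised
over their nonzero support, spliced into the joint adjacency
[[G, K], [K^T, C]] (genes first, then cells), and column-normalised into
the transition matrix W used by random-walk-with-restart propagation.
Zero-sum columns receive a unit self-loop before normalisation so W stays
column-stochastic.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .types import GeneCellNetwork

__all__ = ["minmax_normalize", "column_normalize", "assemble"]


def minmax_normalize(block: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Min-max normalise a weight block over its nonzero support.

    Structural zeros stay zero; a constant nonzero block maps to all ones
    (the association is kept, not destroyed).
    """
    out = sp.csr_matrix(block, copy=True).astype(float)
    if out.nnz == 0:
        return out
    lo, hi = out.data.min(), out.data.max()
    if hi == lo:
        out.data = np.ones_like(out.data)
    else:
        out.data = (out.data - lo) / (hi - lo)
    out.eliminate_zeros()  # the minimum maps to 0 and leaves the support
    return out


def column_normalize(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Column-stochastic transition matrix; dangling columns get a self-loop."""
    a = sp.csr_matrix(adjacency, copy=True).astype(float)
    col_sums = np.asarray(a.sum(axis=0)).ravel()
    dangling = np.flatnonzero(col_sums == 0)
    if dangling.size:
        fix = sp.coo_matrix(
            (np.ones(dangling.size), (dangling, dangling)), shape=a.shape
        )
        a = (a + fix).tocsr()
        col_sums[dangling] = 1.0
    scale = sp.diags(1.0 / col_sums)
    return (a @ scale).tocsr()


def assemble(
    G: sp.spmatrix,
    C: sp.spmatrix,
    K: sp.spmatrix,
    genes: list[str] | None = None,
    cells: list[str] | None = None,
    normalize_blocks: bool = True,
) -> GeneCellNetwork:
    """Splice the three blocks and build the column-stochastic W.

    ``normalize_blocks=False`` trusts the caller's blocks to be on the
    [0, 1] scale already (e.g. when re-reading a written network).
    """
    G, C, K = sp.csr_matrix(G), sp.csr_matrix(C), sp.csr_matrix(K)
    m, n = K.shape
    if G.shape != (m, m) or C.shape != (n, n):
        raise ValueError(
            f"block dimensions incompatible: G{G.shape}, C{C.shape}, K{K.shape}"
        )
    if genes is None:
        genes = [f"gene{i}" for i in range(m)]
    if cells is None:
        cells = [f"cell{j}" for j in range(n)]
    if normalize_blocks:
        G, C, K = minmax_normalize(G), minmax_normalize(C), minmax_normalize(K)
    joint = sp.bmat([[G, K], [K.T, C]], format="csr")
    W = column_normalize(joint)
    return GeneCellNetwork(genes=list(genes), cells=list(cells), G=G, C=C, K=K, W=W)
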