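"""Multi-omics fusion of two gene-cell association networks.

Edge weights (min-max normalised, in [0, 1]) are treated as significance
indicators and mapped to pseudo p-values p = 1 - w.  Edges present in
both networks get a single combined weight 1 - p_combined, where
p_combined comes from Brown's method: X = -2(ln p1 + ln p2) follows a
scaled chi-square whose scale and degrees of freedom are moment-matched
using E[X] = 4 and Var[X] = 8 + 2 cov(-2 ln p1, -2 ln p2), the covariance
estimated as 4 times the empirical correlation of the log-transformed
shared-edge vectors (so identical inputs give back the single-test
p-value exactly, and independent inputs reduce to Fisher's method).
Edges unique to one network carry over unchanged with a provenance flag.
Both networks must be built over the same cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import chi2

from .assembly import assemble, minmax_normalize
from .types import GeneCellNetwork

__all__ = ["FusedNetwork", "weights_to_pvalues", "brown_combine", "fisher_combine", "fuse"]

_EPS = 1e-12


@dataclass
class FusedNetwork:
    network: GeneCellNetwork
    provenance: dict[tuple[str, str], str]  # (node, node) -> rna_only / atac_only / shared


def weights_to_pvalues(weights: np.ndarray) -> np.ndarray:
    """Pseudo p-values p = clip(1 - w, eps, 1); monotone decreasing in w."""
    w = np.asarray(weights, dtype=float)
    return np.clip(1.0 - w, _EPS, 1.0)


def fisher_combine(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Fisher's method: chi-square with 4 df on X = -2(ln p1 + ln p2)."""
    x = -2.0 * (np.log(p1) + np.log(p2))
    return chi2.sf(x, df=4)


def brown_combine(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Brown's dependent-test combination of two pseudo p-value vectors.

    Falls back to Fisher with a warning when fewer than two edges are
    available (covariance not estimable) or the variance estimate is
    degenerate.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p-value vectors must share shape")
    t1, t2 = -2.0 * np.log(p1), -2.0 * np.log(p2)
    x = t1 + t2
    if p1.size < 2:
        warnings.warn("fewer than 2 shared edges; falling back to Fisher's method")
        return chi2.sf(x, df=4)
    s1, s2 = t1.std(), t2.std()
    if s1 == 0 or s2 == 0:
        rho = 1.0 if np.allclose(t1, t2) else 0.0
    else:
        rho = float(np.corrcoef(t1, t2)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    mean_x = 4.0  # two chi^2_2 variates
    var_x = 8.0 + 2.0 * 4.0 * rho  # null variance 4 per test, scaled by correlation
    if var_x <= 0:
        warnings.warn("non-positive Brown variance estimate; falling back to Fisher")
        return chi2.sf(x, df=4)
    c = var_x / (2.0 * mean_x)
    f = 2.0 * mean_x**2 / var_x
    return chi2.sf(x / c, df=f)


def _block_edges(mat: sp.spmatrix, symmetric: bool) -> dict[tuple[int, int], float]:
    coo = mat.tocoo()
    out = {}
    for i, j, w in zip(coo.row, coo.col, coo.data):
        if symmetric:
            if i >= j:
                continue
            out[(int(i), int(j))] = float(w)
        else:
            out[(int(i), int(j))] = float(w)
    return out


def fuse(net_a: GeneCellNetwork, net_b: GeneCellNetwork, tag_a: str = "rna", tag_b: str = "atac") -> FusedNetwork:
    """Merge two same-cell gene-cell networks into one fused network.

    Shared edges are combined by Brown's method per block; unique edges
    carry over unchanged.  The fused blocks are re-min-max normalised and
    the transition matrix rebuilt.
    """
    if set(net_a.cells) != set(net_b.cells):
        if not set(net_a.cells) & set(net_b.cells):
            raise ValueError("cannot fuse networks over disjoint cell sets; multi-omics fusion requires the same cells")
        raise ValueError("cell sets differ; multi-omics fusion requires identical cell sets")
    cells = list(net_a.cells)
    genes = list(dict.fromkeys(list(net_a.genes) + list(net_b.genes)))
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: j for j, c in enumerate(cells)}
    m, n = len(genes), len(cells)

    def remap(net: GeneCellNetwork):
        gmap = [gi[g] for g in net.genes]
        cmap = [ci[c] for c in net.cells]
        blocks = {}
        for name, mat, rows, cols, symm in (
            ("G", net.G, gmap, gmap, True),
            ("C", net.C, cmap, cmap, True),
            ("K", net.K, gmap, cmap, False),
        ):
            edges = {}
            for (i, j), w in _block_edges(mat, symm).items():
                a, b = rows[i], cols[j]
                if symm and a > b:
                    a, b = b, a
                edges[(a, b)] = w
            blocks[name] = edges
        return blocks

    ea, eb = remap(net_a), remap(net_b)
    fused_blocks = {}
    provenance: dict[tuple[str, str], str] = {}
    names_g, names_c = genes, cells

    # pool shared edges across all blocks for one covariance estimate
    shared_keys = {
        blk: sorted(set(ea[blk]) & set(eb[blk])) for blk in ("G", "C", "K")
    }
    all_wa = np.array([ea[blk][k] for blk in ("G", "C", "K") for k in shared_keys[blk]])
    all_wb = np.array([eb[blk][k] for blk in ("G", "C", "K") for k in shared_keys[blk]])
    if all_wa.size:
        combined_p = brown_combine(weights_to_pvalues(all_wa), weights_to_pvalues(all_wb))
        combined_w = 1.0 - combined_p
    combined_iter = iter(combined_w if all_wa.size else [])

    def node_name(blk: str, idx: int, which: int) -> str:
        if blk == "G":
            return names_g[idx]
        if blk == "C":
            return names_c[idx]
        return names_g[idx] if which == 0 else names_c[idx]

    for blk in ("G", "C", "K"):
        edges = {}
        shared = set(shared_keys[blk])
        for k in shared_keys[blk]:
            edges[k] = float(next(combined_iter))
            provenance[(node_name(blk, k[0], 0), node_name(blk, k[1], 1))] = "shared"
        for src, tag in ((ea, f"{tag_a}_only"), (eb, f"{tag_b}_only")):
            for k, w in src[blk].items():
                if k in shared or k in edges:
                    continue
                edges[k] = w
                provenance[(node_name(blk, k[0], 0), node_name(blk, k[1], 1))] = tag
        fused_blocks[blk] = edges

    def to_sparse(edges, shape, symmetric):
        mat = sp.lil_matrix(shape)
        for (i, j), w in edges.items():
            mat[i, j] = w
            if symmetric:
                mat[j, i] = w
        return mat.tocsr()

    G = minmax_normalize(to_sparse(fused_blocks["G"], (m, m), True))
    C = minmax_normalize(to_sparse(fused_blocks["C"], (n, n), True))
    K = minmax_normalize(to_sparse(fused_blocks["K"], (m, n), False))
    net = assemble(G, C, K, genes=genes, cells=cells, normalize_blocks=False)
    return FusedNetwork(network=net, provenance=provenance)
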