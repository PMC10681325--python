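"""Random walk with restart over the gene-cell network and its consumers.

RWR iterates p_{t+1} = (1 - r) W p_t + r p0 from a restart vector p0
uniform over the seed nodes until the L1 difference between successive
iterates falls below tolerance; because W is column-stochastic the map is
a contraction with factor (1 - r), so convergence is guaranteed within
ceil(log(tol / 2) / log(1 - r)) iterations.

Pathway activity: for each pathway, the observed stationary vector with
the pathway's network-mapped genes as seeds is compared per cell against
N permutation runs seeded with uniformly drawn gene sets of the same
size; PAS_ij = 1 - |{runs : p'_j >= p_ij}| / N.

Gene modules: the observed run seeds a phenotype's cells; permutations
draw equal-size random cell sets; each gene's p-value uses the add-one
permutation estimator (1 + count) / (N + 1), and the module is the set of
genes below the significance threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .types import GeneCellNetwork, GeneSetCollection, PathwayScoreMatrix, PhenotypeTable

__all__ = [
    "RWRConfig",
    "GeneModule",
    "rwr",
    "rwr_exact",
    "contraction_bound",
    "pathway_scores",
    "gene_modules",
    "phenotype_propensity",
    "pathway_gene_importance",
]


@dataclass
class RWRConfig:
    r: float = 0.7
    tol: float = 1e-6
    n_perm: int = 100
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError("restart probability r must lie in (0, 1)")
        if self.tol <= 0 or self.n_perm < 1:
            raise ValueError("tol must be > 0 and n_perm >= 1")


@dataclass
class GeneModule:
    phenotype: str
    scores: dict[str, float]  # gene -> stationary probability
    p_values: dict[str, float]  # gene -> permutation p-value
    members: list[str]  # genes with p < threshold
    threshold: float = 0.01


def contraction_bound(r: float, tol: float) -> int:
    """Iteration cap implied by the (1 - r) contraction in L1."""
    return math.ceil(math.log(tol / 2.0) / math.log(1.0 - r))


def _restart_vector(net: GeneCellNetwork, seeds) -> np.ndarray:
    index = {name: i for i, name in enumerate(net.node_names)}
    missing = [s for s in seeds if s not in index]
    if missing:
        raise ValueError(f"seed nodes absent from the network: {missing[:10]}")
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    p0 = np.zeros(net.n_nodes)
    for s in seeds:
        p0[index[s]] = 1.0
    return p0 / p0.sum()


def rwr(net: GeneCellNetwork, seeds, cfg: RWRConfig | None = None) -> np.ndarray:
    """Stationary probability vector of the restart walk from ``seeds``.

    ``seeds`` may be node names or a precomputed restart vector.  Returns
    a vector over the joint node set (genes first) summing to 1.
    """
    if cfg is None:
        cfg = RWRConfig()
    p0 = seeds if isinstance(seeds, np.ndarray) else _restart_vector(net, seeds)
    W = net.W
    r = cfg.r
    p = p0.copy()
    cap = min(cfg.max_iter, contraction_bound(r, cfg.tol) + 1)
    for _ in range(cap):
        p_next = (1.0 - r) * (W @ p) + r * p0
        if np.abs(p_next - p).sum() < cfg.tol:
            return p_next
        p = p_next
    return p


def rwr_exact(net: GeneCellNetwork, seeds, r: float = 0.7) -> np.ndarray:
    """Closed-form stationary vector r (I - (1-r) W)^{-1} p0.

    Direct dense solve; intended as an oracle / fallback for networks up
    to a few thousand nodes.
    """
    p0 = seeds if isinstance(seeds, np.ndarray) else _restart_vector(net, seeds)
    n = net.n_nodes
    A = np.eye(n) - (1.0 - r) * net.W.toarray()
    return r * np.linalg.solve(A, p0)


def _sample_distinct_sets(rng, pool: np.ndarray, size: int, n_perm: int, forbidden: frozenset):
    """Uniform same-size subsets of ``pool``, avoiding ``forbidden`` when possible."""
    can_avoid = math.comb(len(pool), size) > 1
    out = []
    for _ in range(n_perm):
        for _attempt in range(100):
            pick = rng.choice(pool, size=size, replace=False)
            if not can_avoid or frozenset(pick) != forbidden:
                break
        out.append(pick)
    return out


def pathway_scores(
    net: GeneCellNetwork,
    pathways: GeneSetCollection,
    cfg: RWRConfig | None = None,
    min_genes: int = 3,
    max_genes: int = 500,
) -> PathwayScoreMatrix:
    """Permutation-adjusted pathway activity scores, pathway x cell.

    Pathways mapping to fewer than ``min_genes`` network genes are skipped
    with a warning.  The comparison is per cell: p' is that cell's vector
    of permuted stationary values across the N runs.
    """
    if cfg is None:
        cfg = RWRConfig()
    if len(pathways) == 0:
        raise ValueError("empty gene-set collection")
    rng = np.random.default_rng(cfg.seed)
    gene_set = set(net.genes)
    gene_pool = np.array(net.genes)
    m = len(net.genes)
    n = len(net.cells)
    rows, names, seed_counts = [], [], {}
    perm_cache: dict[int, np.ndarray] = {}  # permuted cell-scores per seed size
    for name, genes in pathways:
        mapped = [g for g in genes if g in gene_set]
        if not min_genes <= len(mapped) <= max_genes:
            warnings.warn(
                f"pathway {name!r}: {len(mapped)} mapped genes outside "
                f"[{min_genes}, {max_genes}]; skipped"
            )
            continue
        size = len(mapped)
        observed = rwr(net, mapped, cfg)[m : m + n]
        if size not in perm_cache:
            perm = np.empty((cfg.n_perm, n))
            sets = _sample_distinct_sets(rng, gene_pool, size, cfg.n_perm, frozenset(mapped))
            for k, pick in enumerate(sets):
                perm[k] = rwr(net, list(pick), cfg)[m : m + n]
            perm_cache[size] = perm
        perm = perm_cache[size]
        pas = 1.0 - (perm >= observed[None, :]).sum(axis=0) / cfg.n_perm
        rows.append(pas)
        names.append(name)
        seed_counts[name] = size
    if not rows:
        raise ValueError("no pathway mapped enough genes to be scored")
    return PathwayScoreMatrix(np.vstack(rows), names, list(net.cells), seed_counts)


def gene_modules(
    net: GeneCellNetwork,
    phen: PhenotypeTable,
    cfg: RWRConfig | None = None,
    p_threshold: float = 0.01,
) -> dict[str, GeneModule]:
    """Cell-phenotype-associated gene modules via cell-seeded RWR.

    Per phenotype: observed run seeds its cells; N permutations draw
    equal-size random cell sets; per-gene p = (1 + |{p' >= p_obs}|) / (N+1);
    the module is the genes with p < ``p_threshold``.
    """
    if cfg is None:
        cfg = RWRConfig()
    phen.validate_against(net.cells)
    rng = np.random.default_rng(cfg.seed)
    m = len(net.genes)
    cell_pool = np.array(net.cells)
    modules: dict[str, GeneModule] = {}
    perm_cache: dict[int, np.ndarray] = {}
    for label in phen.labels():
        cells = [c for c in phen.cells_of(label) if c in set(net.cells)]
        if not cells:
            raise ValueError(f"phenotype {label!r} has no cells in the network")
        size = len(cells)
        observed = rwr(net, cells, cfg)[:m]
        if size not in perm_cache:
            if size >= len(cell_pool):
                warnings.warn(
                    f"phenotype {label!r} uses every network cell; permutations are degenerate"
                )
            perm = np.empty((cfg.n_perm, m))
            sets = _sample_distinct_sets(rng, cell_pool, min(size, len(cell_pool)), cfg.n_perm, frozenset(cells))
            for k, pick in enumerate(sets):
                perm[k] = rwr(net, list(pick), cfg)[:m]
            perm_cache[size] = perm
        perm = perm_cache[size]
        counts = (perm >= observed[None, :]).sum(axis=0)
        pvals = (1.0 + counts) / (cfg.n_perm + 1.0)
        members = [g for g, p in zip(net.genes, pvals) if p < p_threshold]
        modules[label] = GeneModule(
            phenotype=label,
            scores=dict(zip(net.genes, observed.tolist())),
            p_values=dict(zip(net.genes, pvals.tolist())),
            members=members,
            threshold=p_threshold,
        )
    return modules


def phenotype_propensity(modules: dict[str, GeneModule] | list[GeneModule]) -> dict[str, dict[str, float]]:
    """Per-gene expression propensity across the phenotypes where it is significant.

    For each gene significant in >= 1 module, the association scores over
    those phenotypes are normalised to sum to 1.
    """
    mods = list(modules.values()) if isinstance(modules, dict) else list(modules)
    out: dict[str, dict[str, float]] = {}
    genes = {g for mod in mods for g in mod.members}
    for g in genes:
        hits = {mod.phenotype: mod.scores[g] for mod in mods if g in mod.members}
        total = sum(hits.values())
        out[g] = {ph: s / total for ph, s in hits.items()}
    return out


def pathway_gene_importance(
    net: GeneCellNetwork,
    pathway_genes,
    phenotype_cells=None,
    cfg: RWRConfig | None = None,
    min_genes: int = 3,
) -> tuple[dict[str, float], sp.csr_matrix]:
    """Importance of each pathway gene: stationary probability under a
    cell-seeded walk (the phenotype's cells, or all cells if none given).

    Also returns the pathway-restricted gene-gene subnetwork for export.
    """
    if cfg is None:
        cfg = RWRConfig()
    gene_set = set(net.genes)
    mapped = [g for g in pathway_genes if g in gene_set]
    if len(mapped) < min_genes:
        raise ValueError(f"pathway maps to {len(mapped)} < {min_genes} network genes")
    seeds = list(phenotype_cells) if phenotype_cells is not None else list(net.cells)
    p = rwr(net, seeds, cfg)
    gi = net.gene_index()
    importance = {g: float(p[gi[g]]) for g in mapped}
    idx = [gi[g] for g in mapped]
    subnet = net.G[idx][:, idx].tocsr()
    return importance, subnet
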