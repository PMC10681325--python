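"""Correlation networks and their variational-graph-autoencoder refinement.

``build_correlation_network`` turns a gene-cell matrix into a gene-gene or
cell-cell network: Pearson correlations over the chosen axis, with an
empirical-p rule per node — partner j of node i survives iff the fraction
of i's positive correlations strictly exceeding P_ij is below alpha —
and the union of the per-node survivor sets symmetrised into an
adjacency whose edge weights are the correlations themselves.

``train_vgae`` refines such a network with a two-layer graph-convolution
variational autoencoder: shared first layer, Gaussian latent per node,
inner-product decoder sigmoid(z_i^T z_j), ELBO = reweighted Bernoulli
reconstruction minus KL to a standard normal.  Convolution runs on the
binarised adjacency (with self-loops added before symmetric
normalisation); the refined network keeps sigmoid(z_i^T z_j) on pairs
that either had an input edge or are newly predicted at >= 0.5.
Implemented in NumPy with explicit gradients; deterministic given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .types import GeneCellMatrix

__all__ = [
    "CorrelationNetwork",
    "VGAEConfig",
    "threshold_correlations",
    "build_correlation_network",
    "normalized_adjacency",
    "gcn_encode",
    "inner_product_decode",
    "train_vgae",
]


@dataclass
class CorrelationNetwork:
    """Symmetric nonnegative-weight network over gene or cell nodes."""

    nodes: list[str]
    adjacency: sp.csr_matrix
    kind: str  # "gene" or "cell"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "cell"):
            raise ValueError("kind must be 'gene' or 'cell'")
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_correlation_network(
    x: GeneCellMatrix, axis: str = "gene", alpha: float = 0.05
) -> CorrelationNetwork:
    """Pearson-correlation network with per-node empirical-p thresholding.

    For node i with positive correlations to candidates j, the empirical
    p-value of j is |{k : P_ik > P_ij}| / |{k : P_ik > 0}|; j is kept iff
    p < alpha.  Edges are the union over both endpoints; retained weight
    is the correlation itself.  Constant rows (undefined correlation) are
    isolated with a warning.
    """
    dense = x.toarray()
    data = dense if axis == "gene" else dense.T
    names = list(x.genes) if axis == "gene" else list(x.cells)
    n = data.shape[0]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 observations per correlation")
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant {axis} rows left isolated")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    return CorrelationNetwork(names, threshold_correlations(corr, alpha), axis)


def threshold_correlations(corr: np.ndarray, alpha: float = 0.05) -> sp.csr_matrix:
    """Apply the per-node empirical-p rule to a zero-diagonal correlation matrix.

    Keeps partner j of node i iff |{k : P_ik > P_ij}| / |{k : P_ik > 0}| <
    alpha among i's positive correlations, then symmetrises by union.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    adj = sp.lil_matrix((n, n))
    for i in range(n):
        row = corr[i]
        pos = row > 0
        n_pos = int(pos.sum())
        if n_pos == 0:
            continue
        for j in np.flatnonzero(pos):
            p = np.count_nonzero(row > row[j]) / n_pos
            if p < alpha:
                adj[i, j] = row[j]
                adj[j, i] = row[j]
    return adj.tocsr()


@dataclass
class VGAEConfig:
    latent_dim: int = 16
    hidden_dim: int = 32
    lr: float = 0.01
    iters: int = 300
    seed: int = 0
    keep_threshold: float = 0.5
    keep_input_edges: bool = True


def normalized_adjacency(adjacency: sp.spmatrix) -> np.ndarray:
    """Symmetric GCN normalisation of the binarised adjacency with self-loops.

    A~ = D^{-1/2} (A + I) D^{-1/2}; the self-loop keeps isolated nodes
    well-defined.
    """
    a = (adjacency != 0).astype(float).toarray()
    np.fill_diagonal(a, 0.0)
    a = a + np.eye(a.shape[0])
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return (a * dinv[:, None]) * dinv[None, :]


def _forward(a_norm, feats, W0, W1_mu, W1_sig):
    pre = a_norm @ feats @ W0
    h = np.maximum(pre, 0.0)
    ah = a_norm @ h
    mu = ah @ W1_mu
    log_sigma = ah @ W1_sig
    return pre, h, ah, mu, log_sigma


def gcn_encode(
    net: CorrelationNetwork,
    features: np.ndarray,
    W0: np.ndarray,
    W1_mu: np.ndarray,
    W1_sig: np.ndarray,
    eps: np.ndarray | None = None,
):
    """Two-layer GCN encoder with shared first-layer weights.

    Returns (mu, log_sigma, Z); Z = mu + exp(log_sigma) * eps during
    training (eps supplied) and Z = mu at inference (eps None).
    """
    a_norm = normalized_adjacency(net.adjacency)
    _, _, _, mu, log_sigma = _forward(a_norm, features, W0, W1_mu, W1_sig)
    z = mu if eps is None else mu + np.exp(log_sigma) * eps
    return mu, log_sigma, z


def inner_product_decode(z: np.ndarray) -> np.ndarray:
    """Edge-probability matrix sigmoid(Z Z^T); symmetric, entries in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-(z @ z.T)))


def train_vgae(
    net: CorrelationNetwork,
    features: np.ndarray,
    cfg: VGAEConfig | None = None,
    **kwargs,
) -> tuple[CorrelationNetwork, dict]:
    """Train the VGAE and return the refined network plus diagnostics.

    The reconstruction term is a positive-class-reweighted Bernoulli
    log-likelihood over all node pairs (no negative sampling, for
    determinism); the KL term to N(0, I) is averaged over nodes.  The
    refined adjacency holds sigmoid(z_i^T z_j) where the input had an edge
    or the prediction clears ``keep_threshold``; the diagonal is dropped.
    """
    if cfg is None:
        cfg = VGAEConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    n = net.n_nodes
    feats = np.asarray(features, dtype=float)
    if feats.shape[0] != n:
        raise ValueError("feature rows must match node order")
    a_bin = (net.adjacency != 0).astype(float).toarray()
    np.fill_diagonal(a_bin, 0.0)
    target = a_bin + np.eye(n)  # self-loops are positive examples
    a_norm = normalized_adjacency(net.adjacency)

    n_pos = target.sum()
    n_all = float(n * n)
    pos_weight = (n_all - n_pos) / max(n_pos, 1.0)
    norm = n_all / (2.0 * max(n_all - n_pos, 1.0))

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    W0 = glorot(feats.shape[1], cfg.hidden_dim)
    W1_mu = glorot(cfg.hidden_dim, cfg.latent_dim)
    W1_sig = glorot(cfg.hidden_dim, cfg.latent_dim)
    params = [W0, W1_mu, W1_sig]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    elbo_trace = np.empty(cfg.iters)
    kl_trace = np.empty(cfg.iters)
    for it in range(cfg.iters):
        pre, h, ah, mu, log_sigma = _forward(a_norm, feats, W0, W1_mu, W1_sig)
        eps = rng.standard_normal(mu.shape)
        sigma = np.exp(log_sigma)
        z = mu + sigma * eps
        logits = z @ z.T
        p = 1.0 / (1.0 + np.exp(-logits))
        # weighted BCE (positive class upweighted), mean over pairs
        w = np.where(target > 0, pos_weight, 1.0)
        eps_num = 1e-12
        bce = -(w * (target * np.log(p + eps_num) + (1 - target) * np.log(1 - p + eps_num))).mean()
        recon = norm * bce
        # KL scaled per node pair, matching the reconstruction term's mean
        kl = -0.5 / n * np.mean(np.sum(1 + 2 * log_sigma - mu**2 - sigma**2, axis=1))
        loss = recon + kl
        if not np.isfinite(loss):
            raise FloatingPointError(f"VGAE loss diverged at iteration {it}")
        elbo_trace[it] = -loss
        kl_trace[it] = kl

        g_logits = norm * w * (p - target) / n_all  # d(recon)/d(logits)
        g_z = (g_logits + g_logits.T) @ z
        g_mu = g_z + mu / n_all
        g_log_sigma = g_z * eps * sigma + (sigma**2 - 1.0) / n_all
        g_ah = g_mu @ W1_mu.T + g_log_sigma @ W1_sig.T
        gW1_mu = ah.T @ g_mu
        gW1_sig = ah.T @ g_log_sigma
        g_h = a_norm.T @ g_ah
        g_pre = g_h * (pre > 0)
        gW0 = (a_norm @ feats).T @ g_pre
        grads = [gW0, gW1_mu, gW1_sig]
        t = it + 1
        for i, (prm, grd) in enumerate(zip(params, grads)):
            adam_m[i] = 0.9 * adam_m[i] + 0.1 * grd
            adam_v[i] = 0.999 * adam_v[i] + 0.001 * grd**2
            prm -= cfg.lr * (adam_m[i] / (1 - 0.9**t)) / (np.sqrt(adam_v[i] / (1 - 0.999**t)) + 1e-8)

    _, _, z = gcn_encode(net, feats, W0, W1_mu, W1_sig, eps=None)  # Z = mu at inference
    probs = inner_product_decode(z)
    keep = probs >= cfg.keep_threshold
    if cfg.keep_input_edges:
        keep |= a_bin > 0
    np.fill_diagonal(keep, False)
    refined = np.where(keep, probs, 0.0)
    refined = (refined + refined.T) / 2.0  # numerically symmetric
    info = {
        "elbo_trace": elbo_trace,
        "kl_trace": kl_trace,
        "weights": {"W0": W0, "W1_mu": W1_mu, "W1_sig": W1_sig},
        "latent": z,
    }
    return CorrelationNetwork(list(net.nodes), sp.csr_matrix(refined), net.kind), info
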