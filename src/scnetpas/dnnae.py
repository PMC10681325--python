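"""TRS-regularised deep autoencoder for gene-cell association inference.

Two small MLP encoders compress the expression matrix X (m genes x n
cells): the gene encoder maps rows of X to E_g (m x d), the cell encoder
maps rows of X^T to E_c (n x d).  A matrix-factorisation decoder
reconstructs X' = E_g E_c^T, and training minimises a squared error
re-weighted by the transcriptional-regulation-state matrix:

    loss = (1 - a) * sum((X' - X)^2) + a * sum((X' - X)^2 * S~)

where S~ is the TRS matrix with each gene's row divided by its maximum
state so entries lie in [0, 1], and a in [0, 1] balances the plain and
TRS-weighted terms.  Optimisation is full-batch Adam with hand-written
gradients; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ltmg import TRSMatrix
from .types import GeneCellMatrix

__all__ = ["DNNAEConfig", "EmbeddingSet", "encode", "decode", "trs_loss", "train", "scale_trs"]


@dataclass
class DNNAEConfig:
    d: int = 50
    hidden_dims: tuple[int, ...] = (256,)
    activation: str = "tanh"
    a: float = 0.5
    lr: float = 1e-3
    iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("regularization weight a must lie in [0, 1]")
        if self.d < 1 or self.lr <= 0:
            raise ValueError("d must be >= 1 and lr > 0")


@dataclass
class EmbeddingSet:
    gene_embeddings: np.ndarray  # (m, d)
    cell_embeddings: np.ndarray  # (n, d)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gene_embeddings).all() and np.isfinite(self.cell_embeddings).all()):
            raise ValueError("embeddings contain non-finite entries")
        if self.gene_embeddings.shape[1] != self.cell_embeddings.shape[1]:
            raise ValueError("gene and cell embedding dimensions differ")


_ACTS = {
    "tanh": (np.tanh, lambda h: 1.0 - h**2),  # derivative in terms of output
    "relu": (lambda x: np.maximum(x, 0.0), lambda h: (h > 0).astype(float)),
    "identity": (lambda x: x, lambda h: np.ones_like(h)),
}


class _MLP:
    """Stacked affine + activation layers with explicit backprop.

    The activation applies to hidden layers; the final (embedding) layer
    is linear so the factorization decoder can represent arbitrary scales.
    """

    def __init__(self, dims: list[int], activation: str, rng: np.random.Generator):
        self.act, self.dact = _ACTS[activation]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def _is_last(self, i: int) -> bool:
        return i == len(self.W) - 1

    def forward(self, x: np.ndarray):
        hs = [x]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            pre = hs[-1] @ W + b
            hs.append(pre if self._is_last(i) else self.act(pre))
        return hs

    def backward(self, hs, grad_out):
        gW, gb = [], []
        g = grad_out
        for i in reversed(range(len(self.W))):
            if not self._is_last(i):
                g = g * self.dact(hs[i + 1])
            gW.append(hs[i].T @ g)
            gb.append(g.sum(axis=0))
            if i:
                g = g @ self.W[i].T
        return gW[::-1], gb[::-1]

    def params(self):
        return self.W + self.b


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def scale_trs(s_trs: TRSMatrix | np.ndarray) -> np.ndarray:
    """Divide each gene's TRS row by its max state so entries lie in [0, 1]."""
    states = s_trs.states.toarray() if isinstance(s_trs, TRSMatrix) else np.asarray(s_trs, float)
    states = states.astype(float)
    row_max = states.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(row_max > 0, states / row_max, 0.0)
    return scaled


def trs_loss(x: np.ndarray, xprime: np.ndarray, s_scaled: np.ndarray, a: float) -> float:
    """(1-a) * SSE + a * TRS-weighted SSE (element-wise weights in [0, 1])."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    resid2 = (xprime - x) ** 2
    return float((1.0 - a) * resid2.sum() + a * (resid2 * s_scaled).sum())


def _build(x_dense: np.ndarray, cfg: DNNAEConfig):
    m, n = x_dense.shape
    rng = np.random.default_rng(cfg.seed)
    gene_net = _MLP([n, *cfg.hidden_dims, cfg.d], cfg.activation, rng)
    cell_net = _MLP([m, *cfg.hidden_dims, cfg.d], cfg.activation, rng)
    return gene_net, cell_net


def encode(x: GeneCellMatrix, cfg: DNNAEConfig) -> EmbeddingSet:
    """Embeddings from freshly initialised (untrained) encoders; deterministic given seed."""
    dense = x.toarray()
    if not np.isfinite(dense).all():
        raise ValueError("input matrix contains non-finite values")
    gene_net, cell_net = _build(dense, cfg)
    return EmbeddingSet(gene_net.forward(dense)[-1], cell_net.forward(dense.T)[-1])


def decode(e: EmbeddingSet) -> np.ndarray:
    """Matrix-factorisation decoder: X' = E_g E_c^T."""
    return e.gene_embeddings @ e.cell_embeddings.T


def train(
    x: GeneCellMatrix | np.ndarray,
    s_trs: TRSMatrix | np.ndarray,
    cfg: DNNAEConfig,
) -> tuple[EmbeddingSet, np.ndarray, np.ndarray]:
    """Train the autoencoder; returns (embeddings, X', per-iteration loss).

    Full-batch Adam for ``cfg.iters`` steps.  Aborts with a diagnostic if
    the loss leaves the finite range.
    """
    dense = x.toarray() if isinstance(x, GeneCellMatrix) else np.asarray(x, float)
    if not np.isfinite(dense).all():
        raise ValueError("input matrix contains non-finite values")
    s_scaled = scale_trs(s_trs)
    if s_scaled.shape != dense.shape:
        raise ValueError("TRS matrix shape does not match expression matrix")
    gene_net, cell_net = _build(dense, cfg)
    params = gene_net.params() + cell_net.params()
    opt = _Adam(params, cfg.lr)
    weight = (1.0 - cfg.a) + cfg.a * s_scaled  # element-wise loss weights
    trace = np.empty(cfg.iters)
    eg = ec = None
    for it in range(cfg.iters):
        hs_g = gene_net.forward(dense)
        hs_c = cell_net.forward(dense.T)
        eg, ec = hs_g[-1], hs_c[-1]
        resid = eg @ ec.T - dense
        loss = float((weight * resid**2).sum())
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss diverged at iteration {it}: {loss}")
        trace[it] = loss
        grad = 2.0 * weight * resid
        gW_g, gb_g = gene_net.backward(hs_g, grad @ ec)
        gW_c, gb_c = cell_net.backward(hs_c, grad.T @ eg)
        opt.step(params, gW_g + gb_g + gW_c + gb_c)
    emb = EmbeddingSet(eg, ec)
    return emb, decode(emb), trace
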