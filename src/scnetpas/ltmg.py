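"""Left-truncated mixture-Gaussian (LTMG) modelling of per-gene expression.

Each gene's normalised expression across cells is modelled as a K-component
Gaussian mixture in which observations below a resolution threshold zcut
are censored: a censored observation contributes the mixture's CDF mass
below zcut, an observed value contributes the usual Gaussian density.  EM
with censored-data sufficient statistics maximises this likelihood; K is
chosen by BIC.  The fitted model converts expression to discrete
transcriptional-regulation-state (TRS) labels {0, 1, ..., K}: 0 below
zcut, otherwise the 1-based index (components sorted by ascending mean)
of the maximum-posterior component, with higher states corresponding to
higher-mean components, i.e. more confidently active expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .types import GeneCellMatrix

__all__ = [
    "LTMGFit",
    "TRSMatrix",
    "estimate_zcut",
    "fit_ltmg",
    "select_k",
    "assign_trs",
    "fit_trs_matrix",
]

SIGMA_FLOOR = 1e-4
EM_TOL = 1e-6
EM_MAX_ITER = 500


@dataclass
class LTMGFit:
    """One gene's fitted mixture: weights/means/sds sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    zcut: float
    loglik: float
    bic: float
    converged: bool = True
    fittable: bool = True
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return len(self.weights)

    def __post_init__(self) -> None:
        if self.fittable:
            assert abs(self.weights.sum() - 1.0) < 1e-9
            assert np.all(self.sds >= SIGMA_FLOOR)
            assert np.all(np.diff(self.means) >= 0)


@dataclass
class TRSMatrix:
    """Integer m x n matrix of TRS labels, 0 meaning below-threshold."""

    states: sp.csr_matrix
    genes: list[str]
    cells: list[str]
    fits: list[LTMGFit] | None = None


def estimate_zcut(values: np.ndarray) -> float:
    """Resolution threshold: the minimum nonzero normalised value.

    All exact zeros fall below it and are treated as censored.  Raises on
    an all-zero gene (caller flags the gene unfittable).
    """
    values = np.asarray(values, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("gene has no nonzero values; unfittable")
    return float(nonzero.min())


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 10) -> np.ndarray:
    """Deterministic 1-D Lloyd k-means seeded at evenly spaced quantiles."""
    centers = np.quantile(values, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    while len(centers) < k:  # duplicate quantiles on ties: spread them
        centers = np.sort(np.append(centers, centers[-1] + SIGMA_FLOOR))
    for _ in range(n_iter):
        lab = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        for i in range(k):
            if np.any(lab == i):
                centers[i] = values[lab == i].mean()
        centers = np.sort(centers)
    return centers


def _censored_moments(zcut: float, mu: np.ndarray, sd: np.ndarray):
    """E[x] and E[x^2] of each component truncated to x < zcut."""
    alpha = (zcut - mu) / sd
    cdf = np.maximum(norm.cdf(alpha), 1e-300)
    lam = norm.pdf(alpha) / cdf  # inverse Mills ratio for the lower tail
    ex = mu - sd * lam
    var = sd**2 * np.clip(1.0 - alpha * lam - lam**2, 0.0, None)
    return ex, var + ex**2, cdf


def fit_ltmg(values: np.ndarray, k: int, zcut: float, max_iter: int = EM_MAX_ITER, tol: float = EM_TOL) -> LTMGFit:
    """Censored-data EM for a K-component left-truncated Gaussian mixture.

    Values below ``zcut`` contribute the mixture CDF mass below zcut to the
    likelihood; values at or above zcut contribute Gaussian densities.
    Returns the best iterate with ``converged=False`` if EM hits the
    iteration cap.
    """
    values = np.asarray(values, dtype=float)
    obs = values[values >= zcut]
    n_cens = int((values < zcut).sum())
    n_total = values.size
    if obs.size == 0:
        raise ValueError("no uncensored observations at or above zcut")

    means = _kmeans_1d(obs, k)
    sds = np.full(k, max(obs.std() if obs.size > 1 else 1.0, SIGMA_FLOOR))
    weights = np.full(k, 1.0 / k)

    trace = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        dens = weights[None, :] * norm.pdf(obs[:, None], means[None, :], sds[None, :])
        dens_sum = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        resp_obs = dens / dens_sum  # (n_obs, k), rows sum to 1
        ll = np.log(dens_sum).sum()
        if n_cens:
            ex_c, ex2_c, cdf_c = _censored_moments(zcut, means, sds)
            mass = weights * cdf_c
            mass_sum = max(mass.sum(), 1e-300)
            resp_cens = mass / mass_sum  # same for every censored obs
            ll += n_cens * np.log(mass_sum)
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        # M-step with censored sufficient statistics
        nk = resp_obs.sum(axis=0)
        sx = resp_obs.T @ obs
        sx2 = resp_obs.T @ obs**2
        if n_cens:
            nk = nk + n_cens * resp_cens
            sx = sx + n_cens * resp_cens * ex_c
            sx2 = sx2 + n_cens * resp_cens * ex2_c
        nk = np.maximum(nk, 1e-12)
        weights = nk / nk.sum()
        means = sx / nk
        sds = np.sqrt(np.maximum(sx2 / nk - means**2, SIGMA_FLOOR**2))

    order = np.argsort(means, kind="stable")
    weights, means, sds = weights[order], means[order], sds[order]
    # prune effectively empty components
    alive = weights > 1e-8
    if not alive.all():
        weights, means, sds = weights[alive], means[alive], sds[alive]
        weights = weights / weights.sum()
    k_eff = len(weights)
    bic = -2.0 * trace[-1] + (3 * k_eff - 1) * np.log(n_total)
    return LTMGFit(
        weights=weights, means=means, sds=sds, zcut=zcut,
        loglik=float(trace[-1]), bic=float(bic), converged=converged,
        loglik_trace=np.asarray(trace),
    )


def select_k(values: np.ndarray, zcut: float | None = None, k_max: int = 5) -> LTMGFit:
    """Fit K = 1..k_max and return the fit minimising BIC.

    k_max is capped so the parameter count (3K-1) does not exceed the
    number of uncensored observations, and by the number of distinct
    uncensored values.
    """
    values = np.asarray(values, dtype=float)
    if zcut is None:
        zcut = estimate_zcut(values)
    obs = values[values >= zcut]
    n_obs = obs.size
    n_distinct = len(np.unique(obs))
    cap = max(1, min(k_max, (n_obs + 1) // 3, n_distinct))
    best: LTMGFit | None = None
    for k in range(1, cap + 1):
        fit = fit_ltmg(values, k, zcut)
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None
    return best


def assign_trs(fit: LTMGFit, values: np.ndarray) -> np.ndarray:
    """Discrete TRS labels for one gene's values under its fitted mixture.

    Below zcut -> 0; otherwise the 1-based index of the maximum-posterior
    component (ascending-mean order), ties resolved to the lower index.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.size, dtype=int)
    if not fit.fittable:
        return out
    active = values >= fit.zcut
    if active.any():
        x = values[active]
        dens = fit.weights[None, :] * norm.pdf(x[:, None], fit.means[None, :], fit.sds[None, :])
        # argmax picks the first (lower) index on exact ties
        out[active] = np.argmax(dens, axis=1) + 1
    return out


def fit_trs_matrix(x: GeneCellMatrix, k_max: int = 5) -> TRSMatrix:
    """Fit the LTMG per gene and assemble the m x n TRS label matrix.

    All-zero genes are flagged unfittable and carry TRS 0 everywhere.
    """
    dense = x.toarray()
    rows = []
    fits: list[LTMGFit] = []
    for values in dense:
        try:
            zcut = estimate_zcut(values)
        except ValueError:
            fits.append(LTMGFit(
                weights=np.empty(0), means=np.empty(0), sds=np.empty(0),
                zcut=np.inf, loglik=np.nan, bic=np.inf, fittable=False,
            ))
            rows.append(np.zeros(values.size, dtype=int))
            continue
        fit = select_k(values, zcut, k_max=k_max)
        fits.append(fit)
        rows.append(assign_trs(fit, values))
    states = sp.csr_matrix(np.vstack(rows))
    return TRSMatrix(states, list(x.genes), list(x.cells), fits)
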