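"""Tied-variance mixture estimation under the scalar constraint.

Expectation-maximization for a Gaussian mixture in which every component SD
is tied to its mean through one shared Weber fraction, ``sigma_k = s * mu_k``.
The constraint couples the components: ``s`` is updated in closed form as the
responsibility-weighted mean of ``(x - mu_k)^2 / mu_k^2``, and each ``mu_k``
by the exact maximizer of its tied objective, the positive root of

    N_k * s^2 * mu^2 + S1_k * mu - S2_k = 0,

with ``S1_k = sum_i w_ik x_i`` and ``S2_k = sum_i w_ik x_i^2`` (the log-sigma
term contributes the linear coefficient).  Both coordinate updates are exact
maximizations, so the log-likelihood is non-decreasing at every iteration.

Component weights are fixed at the neutral 1/K by default (no category is
privileged); ``free_weights=True`` estimates them, for probing that
assumption on data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.cluster import kmeans_plusplus

from .core import (
    DEFAULT_MU_MAX,
    DEFAULT_MU_MIN,
    BoundaryOverlap,
    CategorySystem,
    joint_solve_overlap,
)
from .errors import FeasibilityError, FitError, ParameterError
from .mixture import IOISequence

__all__ = ["FitResult", "SelectKResult", "fit_scalar_mixture", "select_K",
           "estimate_overlaps"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitResult:
    """A fitted scalar-constrained mixture with its fit diagnostics."""

    system: CategorySystem
    loglik: float
    n_iter: int
    converged: bool
    bic: float
    loglik_path: tuple[float, ...] = ()

    def to_json_dict(self) -> dict:
        import json

        out = json.loads(self.system.to_json())
        out.update(
            loglik=self.loglik, n_iter=self.n_iter,
            converged=self.converged, bic=self.bic,
        )
        return out


@dataclass(frozen=True)
class SelectKResult:
    """Component-count selection by BIC, with the full per-K table."""

    K: int
    table: tuple[dict, ...]
    fits: tuple[FitResult, ...]

    @property
    def best(self) -> FitResult:
        return self.fits[self.K - 1]


def _iois_array(iois) -> np.ndarray:
    x = iois.iois if isinstance(iois, IOISequence) else np.asarray(iois, dtype=float)
    if x.ndim != 1 or not np.all(x > 0):
        raise ParameterError("intervals must be a 1-D positive array")
    return x


def _init_means(x: np.ndarray, K: int, seed: int) -> np.ndarray:
    centers, _ = kmeans_plusplus(
        x.reshape(-1, 1), n_clusters=K, random_state=int(seed) % (2**31)
    )
    return np.sort(centers.ravel())


def fit_scalar_mixture(
    iois,
    K: int,
    init_means=None,
    seed: int = 0,
    free_weights: bool = False,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """Fit a K-component scalar-constrained mixture to interval data by EM.

    Parameters
    ----------
    iois : IOISequence or 1-D array of positive ms values
    K : number of components
    init_means : optional explicit initial means; otherwise k-means++ on the
        fixed ``seed`` (the fit is deterministic given data, seed and policy)
    free_weights : estimate component weights instead of fixing them at 1/K
    tol : stop when the log-likelihood gain falls below this

    Returns the fitted :class:`CategorySystem` (means sorted ascending; the
    label-switching ambiguity is resolved by that ordering) plus diagnostics.
    """
    x = _iois_array(iois)
    n = x.size
    if K < 1:
        raise ParameterError(f"K must be at least 1, got {K}")
    if n < 10 * K:
        raise FitError(f"need at least 10*K = {10 * K} intervals, got {n}")
    if np.unique(x).size < K:
        raise FitError(
            f"data has fewer distinct values ({np.unique(x).size}) than components ({K})"
        )

    mu = (
        np.sort(np.asarray(init_means, dtype=float))
        if init_means is not None
        else _init_means(x, K, seed)
    )
    if mu.size != K or np.any(mu <= 0):
        raise ParameterError("init_means must be K positive values")
    # initial s from the nearest-center assignment; floored away from zero
    assign = np.abs(x[:, None] - mu[None, :]).argmin(axis=1)
    s = math.sqrt(max(np.mean(((x - mu[assign]) / mu[assign]) ** 2), 1e-6))
    w = np.full(K, 1.0 / K)

    loglik = -np.inf
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = np.log(w)[None, :] + norm.logpdf(
            x[:, None], loc=mu[None, :], scale=(s * mu)[None, :]
        )
        row_lse = logsumexp(lp, axis=1)
        new_loglik = float(row_lse.sum())
        resp = np.exp(lp - row_lse[:, None])

        gain = new_loglik - loglik
        loglik = new_loglik
        path.append(loglik)
        if 0 <= gain < tol:
            converged = True
            break

        nk = resp.sum(axis=0)
        s1 = resp.T @ x
        s2 = resp.T @ (x * x)
        for k in range(K):
            if nk[k] < 1e-12:
                continue  # starved component keeps its mean
            a = nk[k] * s * s
            mu[k] = (-s1[k] + math.sqrt(s1[k] ** 2 + 4.0 * a * s2[k])) / (2.0 * a)
        s = math.sqrt(
            max(float((resp * ((x[:, None] - mu[None, :]) / mu[None, :]) ** 2).sum())
                / n, 1e-12)
        )
        if free_weights:
            w = np.maximum(nk / n, 1e-12)
            w = w / w.sum()

    order = np.argsort(mu)
    mu, w = mu[order], w[order]
    n_params = K + 1 + (K - 1 if free_weights else 0)
    bic = -2.0 * loglik + n_params * math.log(n)
    system = CategorySystem(
        means=tuple(mu),
        s=s,
        weights=tuple(w / w.sum()),
        mu_min=min(DEFAULT_MU_MIN, float(mu[0])),
        mu_max=max(DEFAULT_MU_MAX, float(mu[-1])),
    )
    return FitResult(
        system=system, loglik=loglik, n_iter=it, converged=converged,
        bic=bic, loglik_path=tuple(path),
    )


def select_K(iois, K_max: int, seed: int = 0, free_weights: bool = False) -> SelectKResult:
    """Fit K = 1..K_max and choose the component count by BIC.

    The full per-K criterion table is reported alongside the choice, so a
    flat or monotone criterion curve (e.g. on uniform data) stays visible.
    """
    if K_max < 1:
        raise ParameterError(f"K_max must be at least 1, got {K_max}")
    fits, rows = [], []
    for K in range(1, K_max + 1):
        res = fit_scalar_mixture(iois, K, seed=seed, free_weights=free_weights)
        fits.append(res)
        rows.append(
            {"K": K, "loglik": res.loglik, "bic": res.bic,
             "converged": res.converged, "n_iter": res.n_iter}
        )
    best = min(rows, key=lambda r: r["bic"])["K"]
    return SelectKResult(K=best, table=tuple(rows), fits=tuple(fits))


def estimate_overlaps(system: CategorySystem) -> list[BoundaryOverlap | None]:
    """Model-implied overlap pair for each adjacent boundary of a fitted system.

    Each pair is the joint solution of the ratio formula and the intersection
    identity at the system's Weber fraction and that boundary's mean ratio.
    Boundaries with no feasible pair yield ``None`` (logged with the reason);
    a single-category system yields an empty list.
    """
    out: list[BoundaryOverlap | None] = []
    for i, r in enumerate(system.ratios()):
        try:
            out.append(joint_solve_overlap(system.s, r))
        except FeasibilityError as err:
            logger.warning("boundary %d (ratio %.4f) infeasible: %s", i + 1, r, err)
            out.append(None)
    return out
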