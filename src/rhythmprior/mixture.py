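"""The generative mixture over inter-onset intervals and Bayesian attribution.

The prior over durations is a K-component Gaussian mixture whose component
SDs obey scalar timing (``sigma_k = s * mu_k``).  An n-event rhythm is a
sequence of n-1 inter-onset intervals (IOIs) modelled as i.i.d. draws from
this mixture; perception attributes each interval to the category with
maximal posterior probability ``p(z=k|d) ∝ phi_k * N(d; mu_k, sigma_k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .core import CategorySystem
from .errors import ParameterError

__all__ = [
    "IOISequence",
    "CategoryAttribution",
    "mixture_density",
    "sample_iois",
    "posterior_category",
    "map_category",
    "ratios_of",
]


@dataclass(frozen=True)
class IOISequence:
    """A sequence of inter-onset intervals in milliseconds.

    ``chain_id`` and ``generation`` are provenance labels used by the CSV
    dialect and the chain simulator; they do not affect any computation.
    Adjacent ratios are always recomputed on demand (see :func:`ratios_of`),
    never stored.
    """

    iois: np.ndarray
    chain_id: str = "chain0"
    generation: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.iois, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ParameterError("an IOI sequence must be a non-empty 1-D array")
        if not np.all(arr > 0):
            raise ParameterError("all inter-onset intervals must be positive")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "iois", arr)

    def __len__(self) -> int:
        return int(self.iois.size)

    @property
    def ratios(self) -> np.ndarray:
        return ratios_of(self)


@dataclass(frozen=True)
class CategoryAttribution:
    """Per-interval category labels (1-based) with their full posteriors."""

    labels: np.ndarray
    posterior: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        post = np.asarray(self.posterior, dtype=float)
        if post.ndim != 2 or labels.shape != (post.shape[0],):
            raise ParameterError("labels must align with posterior rows")
        if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
            raise ParameterError("each posterior row must sum to 1")
        if np.any(labels < 1) or np.any(labels > post.shape[1]):
            raise ParameterError("labels must be 1-based category indices")
        labels = labels.copy()
        labels.flags.writeable = False
        post = post.copy()
        post.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "posterior", post)

    def __len__(self) -> int:
        return int(self.labels.size)


def _component_logpdf(x: np.ndarray, system: CategorySystem) -> np.ndarray:
    """log(phi_k) + log N(x; mu_k, s*mu_k), shape (n, K)."""
    mu = np.asarray(system.means)
    sd = np.asarray(system.sds)
    w = np.asarray(system.weights)
    return np.log(w) + norm.logpdf(x[:, None], loc=mu[None, :], scale=sd[None, :])


def _as_positive_array(x, name: str = "duration") -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(arr > 0):
        raise ParameterError(f"{name} must be positive")
    return arr


def mixture_density(x, system: CategorySystem):
    """Mixture density sum_k phi_k * N(x; mu_k, s*mu_k) at duration(s) x (ms).

    The log-likelihood of an i.i.d. interval sequence is the sum of the log
    of this density over its intervals.
    """
    arr = _as_positive_array(x)
    dens = np.exp(logsumexp(_component_logpdf(arr, system), axis=1))
    return float(dens[0]) if np.isscalar(x) or np.ndim(x) == 0 else dens


def sequence_loglik(seq: IOISequence, system: CategorySystem) -> float:
    """Log-likelihood of an IOI sequence under the mixture (i.i.d. intervals)."""
    return float(logsumexp(_component_logpdf(seq.iois, system), axis=1).sum())


def sample_positive_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Normal draws with non-positive values redrawn (not truncated-renormalized).

    At s = 0.025 a non-positive draw sits ~40 SDs out, so redrawing introduces
    no measurable bias; the loop only matters in large-s stress settings.
    """
    out = rng.normal(mean, sd)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad],
                              np.broadcast_to(sd, out.shape)[bad])
        bad = out <= 0
    return out

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_iois(system: CategorySystem, n: int, seed=None, **meta) -> IOISequence:
    """Draw n i.i.d. intervals: category by weight, then its scalar Gaussian."""
    if not n >= 1:
        raise ParameterError(f"sample size must be at least 1, got {n}")
    rng = _as_rng(seed)
    ks = rng.choice(system.K, size=n, p=np.asarray(system.weights))
    mu = np.asarray(system.means)[ks]
    sd = np.asarray(system.sds)[ks]
    return IOISequence(sample_positive_normal(rng, mu, sd), **meta)


def posterior_category(d, system: CategorySystem) -> np.ndarray:
    """Posterior over categories for duration(s) d, computed in log space.

    Returns shape (K,) for a scalar d, else (n, K).
    """
    arr = _as_positive_array(d)
    lp = _component_logpdf(arr, system)
    post = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
    return post[0] if np.isscalar(d) or np.ndim(d) == 0 else post


def map_category(d, system: CategorySystem):
    """MAP category label(s), 1-based; exact posterior ties go to the lower index."""
    post = np.atleast_2d(posterior_category(d, system))
    labels = post.argmax(axis=1) + 1  # argmax returns the first maximum
    return int(labels[0]) if np.isscalar(d) or np.ndim(d) == 0 else labels


def attribute(d, system: CategorySystem) -> CategoryAttribution:
    """Full attribution (labels + posteriors) for an array of durations."""
    post = np.atleast_2d(posterior_category(d, system))
    return CategoryAttribution(labels=post.argmax(axis=1) + 1, posterior=post)


def ratios_of(sequence) -> np.ndarray:
    """Adjacent interval ratios r_i = d_{i+1}/d_i (n-2 values for n events)."""
    iois = sequence.iois if isinstance(sequence, IOISequence) else np.asarray(
        sequence, dtype=float
    )
    if iois.size < 2:
        raise ParameterError("at least two intervals are needed to form a ratio")
    return iois[1:] / iois[:-1]
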