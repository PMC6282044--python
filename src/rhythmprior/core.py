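"""Closed-form algebra of scalar-timing duration categories.

A duration category k is a Gaussian with mean ``mu_k`` (ms) and standard
deviation ``sigma_k = s * mu_k``, where ``s`` is the Weber fraction of scalar
timing (the coefficient of variation, constant across durations).  Adjacent
categories k and k+1 intersect at a boundary that sits ``c_upper`` SDs above
``mu_k`` and ``c_lower_next`` SDs below ``mu_{k+1}``.  Requiring the two
parameterizations to describe the same x-coordinate yields the ratio of
adjacent means,

    r_k = mu_{k+1} / mu_k = (1 + s * c_upper) / (1 - s * c_lower_next),

well defined only when ``c_lower_next < 1/s``.  Requiring in addition that the
two component densities are *equal* at the boundary (the categorical-perception
reading of the boundary) yields the intersection identity

    c_upper^2 - c_lower_next^2 = 2 * ln(mu_{k+1} / mu_k).

This module houses those identities, the solvers linking them, and the
construction of whole category systems by the mean recursion
``mu_{k+1} = r_k * mu_k`` under the sub-second bound on category means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

from .errors import FeasibilityError, NoRealSolutionError, ParameterError

__all__ = [
    "ScalarTimingParams",
    "BoundaryOverlap",
    "RatioSequence",
    "CategorySystem",
    "sigma_from_mu",
    "ratio_from_overlap",
    "next_mean",
    "intersection_x",
    "intersection_identity_residual",
    "solve_c_lower",
    "joint_solve_overlap",
    "build_category_system",
    "max_categories",
]

#: Empirical estimate of the sub-second Weber fraction for interval timing.
DEFAULT_S = 0.025
#: Range of admissible category means, in ms (sub-second categorical timing).
DEFAULT_MU_MIN = 200.0
DEFAULT_MU_MAX = 1000.0


@dataclass(frozen=True)
class ScalarTimingParams:
    """Weber fraction and the admissible range of category means.

    Parameters
    ----------
    s : float
        Dimensionless Weber fraction, ``sigma = s * mu``.  Default 0.025,
        the empirical sub-second estimate.
    mu_min, mu_max : float
        Bounds on category means, in milliseconds.  Defaults 200 and 1000.
    """

    s: float = DEFAULT_S
    mu_min: float = DEFAULT_MU_MIN
    mu_max: float = DEFAULT_MU_MAX

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ParameterError(f"Weber fraction s must be positive, got {self.s}")
        if not self.mu_min > 0:
            raise ParameterError(f"mu_min must be positive, got {self.mu_min}")
        if not self.mu_min < self.mu_max:
            raise ParameterError(
                f"mu_min must be below mu_max, got [{self.mu_min}, {self.mu_max}]"
            )


@dataclass(frozen=True)
class BoundaryOverlap:
    """Overlap of one adjacent category pair, in SD units.

    ``c_upper`` is the distance (in SDs of the lower category) from the lower
    category's mean up to the boundary; ``c_lower_next`` the distance (in SDs
    of the upper category) from the upper category's mean down to it.
    """

    c_upper: float
    c_lower_next: float

    def __post_init__(self) -> None:
        if not self.c_upper > 0:
            raise ParameterError(f"c_upper must be positive, got {self.c_upper}")
        if not self.c_lower_next > 0:
            raise ParameterError(
                f"c_lower_next must be positive, got {self.c_lower_next}"
            )

    def check_feasible(self, s: float) -> None:
        """Raise unless ``c_lower_next < 1/s`` (the ratio formula's domain)."""
        if not s > 0:
            raise ParameterError(f"Weber fraction s must be positive, got {s}")
        if self.c_lower_next >= 1.0 / s:
            raise FeasibilityError(
                f"c_lower_next={self.c_lower_next} >= 1/s={1.0 / s}: the adjacent-"
                "mean ratio (1 + s*c_upper)/(1 - s*c_lower_next) is not positive"
            )


@dataclass(frozen=True)
class RatioSequence:
    """Ordered ratios r_k = mu_{k+1}/mu_k of an increasing category system."""

    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        for r in self.ratios:
            if not r > 1.0:
                raise ParameterError(
                    f"adjacent-mean ratios of an increasing system must exceed 1, got {r}"
                )

    def __iter__(self) -> Iterator[float]:
        return iter(self.ratios)


def sigma_from_mu(mu: float, s: float) -> float:
    """Scalar-timing SD: ``sigma = s * mu`` (both mu and result in ms)."""
    if not mu > 0:
        raise ParameterError(f"duration mean must be positive, got {mu}")
    if not s > 0:
        raise ParameterError(f"Weber fraction s must be positive, got {s}")
    return s * mu


def ratio_from_overlap(s: float, overlap: BoundaryOverlap) -> float:
    """Adjacent-mean ratio implied by one boundary overlap.

    ``r = (1 + s*c_upper) / (1 - s*c_lower_next)``, defined for
    ``c_lower_next < 1/s`` and always > 1 for positive overlaps.
    """
    overlap.check_feasible(s)
    return (1.0 + s * overlap.c_upper) / (1.0 - s * overlap.c_lower_next)


def next_mean(mu_k: float, r_k: float) -> float:
    """Mean recursion: ``mu_{k+1} = r_k * mu_k``."""
    if not mu_k > 0:
        raise ParameterError(f"category mean must be positive, got {mu_k}")
    if not r_k > 0:
        raise ParameterError(f"ratio must be positive, got {r_k}")
    return r_k * mu_k


def intersection_x(mu: float, s: float, c: float, side: str) -> float:
    """Boundary x-coordinate seen from one category.

    ``side='upper'`` gives ``mu * (1 + s*c)`` (boundary above the mean);
    ``side='lower'`` gives ``mu * (1 - s*c)`` (boundary below the mean).
    """
    if not mu > 0:
        raise ParameterError(f"category mean must be positive, got {mu}")
    if not s > 0:
        raise ParameterError(f"Weber fraction s must be positive, got {s}")
    if c < 0:
        raise ParameterError(f"overlap parameter c must be non-negative, got {c}")
    if side == "upper":
        return mu * (1.0 + s * c)
    if side == "lower":
        if s * c >= 1.0:
            raise ParameterError(
                f"s*c = {s * c} >= 1: lower-side boundary would be non-positive"
            )
        return mu * (1.0 - s * c)
    raise ParameterError(f"side must be 'upper' or 'lower', got {side!r}")


def intersection_identity_residual(
    overlap: BoundaryOverlap, mu_k: float, mu_next: float
) -> float:
    """Residual of the density-equality identity at an adjacent boundary.

    Returns ``c_upper^2 - c_lower_next^2 - 2*ln(mu_next/mu_k)``; zero exactly
    when the two scaled category densities are equal at the boundary.  The
    right side is strictly positive for ``mu_next > mu_k``, so equal overlap
    parameters can never satisfy the identity.
    """
    if not mu_k > 0:
        raise ParameterError(f"category mean must be positive, got {mu_k}")
    if not mu_next > mu_k:
        raise ParameterError(
            f"means must be strictly increasing, got mu_k={mu_k}, mu_next={mu_next}"
        )
    return (
        overlap.c_upper**2
        - overlap.c_lower_next**2
        - 2.0 * math.log(mu_next / mu_k)
    )


def solve_c_lower(c_upper: float, r: float) -> float:
    """Solve the intersection identity for the upper category's lower overlap.

    Given ``c_upper`` and the mean ratio ``r``, returns the unique positive
    root ``sqrt(c_upper^2 - 2*ln r)``.  ``r = 1`` is admitted as the algebraic
    limit (returns ``c_upper``) although a real increasing system needs r > 1.
    """
    if not c_upper > 0:
        raise ParameterError(f"c_upper must be positive, got {c_upper}")
    if not r >= 1.0:
        raise ParameterError(f"mean ratio must be >= 1, got {r}")
    disc = c_upper**2 - 2.0 * math.log(r)
    if disc < 0:
        raise NoRealSolutionError(
            f"c_upper^2 = {c_upper**2:.6g} < 2*ln(r) = {2 * math.log(r):.6g}: "
            "no real overlap solves the intersection identity"
        )
    return math.sqrt(disc)


def joint_solve_overlap(s: float, r: float) -> BoundaryOverlap:
    """Solve the ratio formula and the intersection identity simultaneously.

    Substituting ``c_upper = (r*(1 - s*c_l) - 1)/s`` (the ratio formula) into
    the identity ``c_upper^2 - c_l^2 = 2*ln r`` gives a quadratic in ``c_l``:

        (r^2 - 1)*c_l^2 - (2*r*(r-1)/s)*c_l + (r-1)^2/s^2 - 2*ln r = 0.

    Of the algebraic roots, only those with ``0 < c_l < 1/s`` and a positive
    implied ``c_upper`` describe a real boundary; if two qualify, the smaller
    ``c_l`` (better-separated categories) is returned.
    """
    if not 0 < s < 1:
        raise ParameterError(f"Weber fraction must lie in (0, 1), got {s}")
    if not r > 1.0:
        raise ParameterError(f"mean ratio must exceed 1, got {r}")
    a = r * r - 1.0
    b = -2.0 * r * (r - 1.0) / s
    c0 = (r - 1.0) ** 2 / s**2 - 2.0 * math.log(r)
    disc = b * b - 4.0 * a * c0
    if disc < 0:
        raise FeasibilityError(
            f"no real overlap pair exists for s={s}, r={r} (negative discriminant)"
        )
    sq = math.sqrt(disc)
    candidates = []
    for c_l in ((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)):
        if not 0.0 < c_l < 1.0 / s:
            continue
        c_u = (r * (1.0 - s * c_l) - 1.0) / s
        if c_u > 0.0:
            candidates.append((c_l, c_u))
    if not candidates:
        raise FeasibilityError(
            f"no overlap pair with 0 < c_lower_next < 1/s exists for s={s}, r={r}"
        )
    c_l, c_u = min(candidates)
    return BoundaryOverlap(c_upper=c_u, c_lower_next=c_l)


Schedule = Union[
    float, int, BoundaryOverlap, RatioSequence, Sequence[float], Sequence[BoundaryOverlap]
]


def _ratio_iter(schedule: Schedule, s: float) -> Iterator[float]:
    """Normalize a ratio schedule to an iterator of per-boundary ratios.

    A single ratio or overlap is reused at every boundary (infinite iterator);
    a sequence is consumed once.
    """

    def check(r: float) -> float:
        if not r > 1.0:
            raise ParameterError(
                f"schedule ratios must exceed 1 for an increasing system, got {r}"
            )
        return float(r)

    if isinstance(schedule, BoundaryOverlap):
        r = check(ratio_from_overlap(s, schedule))
        while True:
            yield r
    elif isinstance(schedule, (int, float)):
        r = check(float(schedule))
        while True:
            yield r
    elif isinstance(schedule, RatioSequence):
        yield from schedule.ratios
    else:
        items = list(schedule)
        if not items:
            raise ParameterError("schedule must not be empty")
        for item in items:
            if isinstance(item, BoundaryOverlap):
                yield check(ratio_from_overlap(s, item))
            else:
                yield check(float(item))


@dataclass(frozen=True)
class CategorySystem:
    """An ordered set of scalar-timing duration categories (the mixture prior).

    ``means`` are the category means mu_1 < ... < mu_K in ms; SDs are derived
    as ``s * mu_k`` (never stored, so the scalar constraint cannot be violated
    on disk); ``weights`` default to the neutral 1/K.
    """

    means: tuple[float, ...]
    s: float = DEFAULT_S
    weights: tuple[float, ...] = field(default=())
    mu_min: float = DEFAULT_MU_MIN
    mu_max: float = DEFAULT_MU_MAX

    def __post_init__(self) -> None:
        means = tuple(float(m) for m in self.means)
        if not means:
            raise ParameterError("a category system needs at least one category")
        if not self.s > 0:
            raise ParameterError(f"Weber fraction s must be positive, got {self.s}")
        for m in means:
            if not m > 0:
                raise ParameterError(f"category means must be positive, got {m}")
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ParameterError(f"category means must be strictly increasing: {means}")
        if means[-1] > self.mu_max:
            raise ParameterError(
                f"largest mean {means[-1]} exceeds the bound mu_max={self.mu_max}"
            )
        object.__setattr__(self, "means", means)
        if not self.weights:
            object.__setattr__(self, "weights", (1.0 / len(means),) * len(means))
        else:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(means):
                raise ParameterError("weights and means must have equal length")
            if any(x <= 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ParameterError(f"weights must be positive and sum to 1: {w}")
            object.__setattr__(self, "weights", w)

    @property
    def K(self) -> int:
        return len(self.means)

    @property
    def sds(self) -> tuple[float, ...]:
        """Scalar-timing SDs, derived: sigma_k = s * mu_k."""
        return tuple(self.s * m for m in self.means)

    def ratios(self) -> RatioSequence:
        """Adjacent-mean ratios r_k = mu_{k+1}/mu_k."""
        return RatioSequence(
            tuple(b / a for a, b in zip(self.means, self.means[1:]))
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "s": self.s,
                "means_ms": list(self.means),
                "weights": list(self.weights),
                "mu_min_ms": self.mu_min,
                "mu_max_ms": self.mu_max,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CategorySystem":
        obj = json.loads(text)
        return cls(
            means=tuple(obj["means_ms"]),
            s=float(obj["s"]),
            weights=tuple(obj.get("weights") or ()),
            mu_min=float(obj.get("mu_min_ms", DEFAULT_MU_MIN)),
            mu_max=float(obj.get("mu_max_ms", DEFAULT_MU_MAX)),
        )


def _iterate_means(
    mu_1: float, s: float, schedule: Schedule, bounds: ScalarTimingParams
) -> list[float]:
    if not bounds.mu_min <= mu_1 <= bounds.mu_max:
        raise ParameterError(
            f"mu_1={mu_1} outside the admissible range "
            f"[{bounds.mu_min}, {bounds.mu_max}]"
        )
    means = [float(mu_1)]
    for r in _ratio_iter(schedule, s):
        nxt = next_mean(means[-1], r)
        if nxt > bounds.mu_max:
            break
        means.append(nxt)
    return means


def build_category_system(
    mu_1: float,
    s: float,
    schedule: Schedule,
    bounds: ScalarTimingParams | None = None,
) -> CategorySystem:
    """Build a category system by the mean recursion under the mu_max bound.

    ``schedule`` may be a single ratio or :class:`BoundaryOverlap` (reused at
    every boundary) or a finite sequence of either.  Iteration stops as soon as
    the next mean would exceed ``bounds.mu_max`` (so K is the largest count of
    categories with all means within bound), or when a finite schedule is
    exhausted.  ``bounds`` supplies only the admissible mean range; the Weber
    fraction is always the explicit ``s`` argument.
    """
    if bounds is None:
        bounds = ScalarTimingParams(s=s)
    means = _iterate_means(mu_1, s, schedule, bounds)
    return CategorySystem(
        means=tuple(means), s=s, mu_min=bounds.mu_min, mu_max=bounds.mu_max
    )


def max_categories(
    mu_1: float,
    schedule: Schedule,
    mu_max: float = DEFAULT_MU_MAX,
    s: float = DEFAULT_S,
    mu_min: float | None = None,
) -> int:
    """Number of categories the mean recursion fits below ``mu_max``."""
    lo = mu_min if mu_min is not None else min(DEFAULT_MU_MIN, mu_1)
    bounds = ScalarTimingParams(s=s, mu_min=lo, mu_max=mu_max)
    return len(_iterate_means(mu_1, s, schedule, bounds))
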