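"""Parameter-space exploration: which settings yield small-integer systems?

Grids over the Weber fraction, the overlap/ratio schedule and the first
category mean are expanded into a flat table: each point builds a category
system by the mean recursion, classifies every adjacent-mean ratio against
the nearest small-integer fraction, and flags whether all ratios are small
within tolerance.  Infeasible points are first-class rows with a reason code
(never silently dropped), so the shape of the parameter space — including
where the model breaks down — is mapped.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .chain import DEFAULT_MAX_INT, DEFAULT_RATIO_TOLERANCE, nearest_small_integer_ratio
from .core import (
    BoundaryOverlap,
    CategorySystem,
    ScalarTimingParams,
    build_category_system,
    joint_solve_overlap,
    ratio_from_overlap,
)
from .errors import FeasibilityError, NoRealSolutionError, ParameterError

__all__ = ["grid_explore", "inverse_question", "EXPLORE_COLUMNS"]

EXPLORE_COLUMNS = [
    "s", "mu1_ms", "schedule_kind", "c_upper", "c_lower_next", "K",
    "means_ms", "ratios", "nearest_p", "nearest_q", "deviations",
    "all_small", "feasible", "reason",
]


def _join(values) -> str:
    return ";".join(repr(float(v)) for v in values)


def _classify(system: CategorySystem, tolerance: float, max_int: int) -> dict:
    ratios = list(system.ratios()) if system.K > 1 else []
    nearest = [nearest_small_integer_ratio(r, max_int=max_int) for r in ratios]
    return {
        "K": system.K,
        "means_ms": _join(system.means),
        "ratios": _join(ratios),
        "nearest_p": ";".join(str(m.p) for m in nearest),
        "nearest_q": ";".join(str(m.q) for m in nearest),
        "deviations": _join(m.deviation for m in nearest),
        "all_small": bool(all(m.deviation <= tolerance for m in nearest)),
        "feasible": True,
        "reason": "",
    }


def _infeasible(reason: str) -> dict:
    return {
        "K": 0, "means_ms": "", "ratios": "", "nearest_p": "", "nearest_q": "",
        "deviations": "", "all_small": False, "feasible": False, "reason": reason,
    }


def grid_explore(
    s_values: Sequence[float],
    overlap_or_ratio_grid: Sequence,
    mu1_values: Sequence[float],
    bounds: ScalarTimingParams | None = None,
    tolerance: float = DEFAULT_RATIO_TOLERANCE,
    max_int: int = DEFAULT_MAX_INT,
) -> pd.DataFrame:
    """Exhaustive grid over (s, schedule, mu_1) with per-point classification.

    ``overlap_or_ratio_grid`` entries are either plain ratios (> 1) or
    :class:`BoundaryOverlap` pairs (converted to a ratio at each grid s).
    Each feasible row records the built system's means, ratios and nearest
    small-integer fractions; infeasible rows carry a reason code among
    ``eq_feasibility_violation`` (overlap ratio undefined at this s),
    ``no_real_root``, ``mu1_out_of_bounds`` and ``invalid_ratio``.
    The row set is independent of grid iteration order.
    """
    if not (len(s_values) and len(overlap_or_ratio_grid) and len(mu1_values)):
        raise ParameterError("all exploration grids must be non-empty")
    rows = []
    for s in s_values:
        for entry in overlap_or_ratio_grid:
            for mu1 in mu1_values:
                base = {"s": float(s), "mu1_ms": float(mu1)}
                if isinstance(entry, BoundaryOverlap):
                    base.update(
                        schedule_kind="overlap",
                        c_upper=entry.c_upper,
                        c_lower_next=entry.c_lower_next,
                    )
                else:
                    base.update(
                        schedule_kind="ratio", c_upper=float("nan"),
                        c_lower_next=float("nan"),
                    )
                try:
                    if isinstance(entry, BoundaryOverlap):
                        # feasibility check first so the reason is specific
                        ratio_from_overlap(s, entry)
                    system = build_category_system(mu1, s, entry, bounds)
                    base.update(_classify(system, tolerance, max_int))
                except FeasibilityError:
                    base.update(_infeasible("eq_feasibility_violation"))
                except NoRealSolutionError:
                    base.update(_infeasible("no_real_root"))
                except ParameterError as err:
                    base.update(
                        _infeasible(
                            "mu1_out_of_bounds" if "mu_1" in str(err) or "range" in str(err)
                            else "invalid_ratio"
                        )
                    )
                rows.append(base)
    return pd.DataFrame(rows, columns=EXPLORE_COLUMNS)


def inverse_question(
    mu_1: float, s: float, target_ratios: Sequence[float]
) -> list[BoundaryOverlap]:
    """Overlap pairs required for given target adjacent-mean ratios.

    For each target ratio the jointly solved (c_upper, c_lower_next) pair is
    returned — the values an observer's boundaries would need.  Whether those
    values are psychophysically plausible is reported, not judged.
    ``mu_1`` scales the system but not the overlap algebra; it is accepted so
    callers can phrase the question per starting mean.
    """
    if not mu_1 > 0:
        raise ParameterError(f"mu_1 must be positive, got {mu_1}")
    if not target_ratios:
        raise ParameterError("at least one target ratio is required")
    return [joint_solve_overlap(s, float(r)) for r in target_ratios]
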