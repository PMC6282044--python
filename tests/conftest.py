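import numpy as np
import pytest

import rhythmprior as rp


@pytest.fixture
def default_system() -> rp.CategorySystem:
    """The canonical 3-category ratio-2 system: means 200/400/800 ms, s=0.025."""
    return rp.build_category_system(200.0, 0.025, 2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def scan_joint_overlap(s: float, r: float, step: float = 1e-4):
    """Independent scanning oracle for the joint overlap solve.

    Substitutes the ratio-formula expression for c_upper into the intersection
    identity and scans c_lower over (0, 1/s) for sign changes of the residual,
    then bisects each bracket.  Returns the list of (c_lower, c_upper) roots.
    """
    import math

    def resid(cl):
        cu = (r * (1 - s * cl) - 1) / s
        return cu * cu - cl * cl - 2 * math.log(r)

    grid = np.arange(step, 1 / s, step)
    vals = np.array([resid(c) for c in grid])
    roots = []
    for i in np.where(np.diff(np.sign(vals)) != 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if resid(lo) * resid(mid) <= 0:
                hi = mid
            else:
                lo = mid
        cl = 0.5 * (lo + hi)
        cu = (r * (1 - s * cl) - 1) / s
        if cu > 0:
            roots.append((cl, cu))
    return roots
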