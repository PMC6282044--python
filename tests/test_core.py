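"""Overlap algebra: identities, solvers and category-system construction."""

import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rhythmprior as rp
from conftest import scan_joint_overlap

# (c_lower, c_upper) roots of the joint solve, frozen from the scanning oracle
JOINT_ORACLE = {
    (0.025, 2.0): (13.316016, 13.367968),
    (0.5, 10.0): (1.536092, 2.639081),
    (0.025, 1.5): (7.979740, 8.030391),
}


class TestSigmaFromMu:
    @pytest.mark.parametrize(
        "mu,s,expected", [(1000.0, 0.025, 25.0), (100.0, 0.025, 2.5)]
    )
    def test_scalar_product(self, mu, s, expected):
        assert rp.sigma_from_mu(mu, s) == pytest.approx(expected)

    @pytest.mark.parametrize("mu,s", [(100.0, 0.0), (0.0, 0.025), (-5.0, 0.025)])
    def test_rejects_non_positive(self, mu, s):
        with pytest.raises(rp.ParameterError):
            rp.sigma_from_mu(mu, s)


class TestRatioFromOverlap:
    def test_zero_overlap_limit_is_unity(self):
        r = rp.ratio_from_overlap(
            0.025, rp.BoundaryOverlap(c_upper=1e-12, c_lower_next=1e-12)
        )
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_joint_solved_pair_yields_its_ratio(self):
        cl, cu = JOINT_ORACLE[(0.025, 2.0)]
        r = rp.ratio_from_overlap(0.025, rp.BoundaryOverlap(cu, cl))
        assert r == pytest.approx(2.0, abs=1e-3)

    def test_feasibility_boundary_rejected(self):
        with pytest.raises(rp.FeasibilityError):
            rp.ratio_from_overlap(0.025, rp.BoundaryOverlap(2.0, 40.0))

    def test_non_positive_overlap_rejected(self):
        with pytest.raises(rp.ParameterError):
            rp.BoundaryOverlap(0.0, 2.0)
        with pytest.raises(rp.ParameterError):
            rp.BoundaryOverlap(2.0, -1.0)

    @given(
        s=st.floats(0.005, 0.2),
        cu=st.floats(0.1, 15.0),
        cl=st.floats(0.1, 4.9),
        dcu=st.floats(0.01, 1.0),
        dcl=st.floats(0.01, 0.05),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_both_overlaps(self, s, cu, cl, dcu, dcl):
        base = rp.ratio_from_overlap(s, rp.BoundaryOverlap(cu, cl))
        assert rp.ratio_from_overlap(s, rp.BoundaryOverlap(cu + dcu, cl)) > base
        assert rp.ratio_from_overlap(s, rp.BoundaryOverlap(cu, cl + dcl)) > base


class TestNextMean:
    @pytest.mark.parametrize(
        "mu,r,expected", [(100.0, 2.0, 200.0), (250.0, 1.0, 250.0), (200.0, 1.5, 300.0)]
    )
    def test_recursion_step(self, mu, r, expected):
        assert rp.next_mean(mu, r) == pytest.approx(expected)

    def test_rejects_non_positive(self):
        with pytest.raises(rp.ParameterError):
            rp.next_mean(-100.0, 2.0)
        with pytest.raises(rp.ParameterError):
            rp.next_mean(100.0, 0.0)


class TestIntersectionX:
    def test_hand_arithmetic_upper(self):
        assert rp.intersection_x(100.0, 0.025, 2.5, "upper") == pytest.approx(106.25)

    def test_zero_offset_returns_mean(self):
        assert rp.intersection_x(321.0, 0.025, 0.0, "upper") == 321.0
        assert rp.intersection_x(321.0, 0.025, 0.0, "lower") == 321.0

    def test_lower_side_cannot_cross_zero(self):
        with pytest.raises(rp.ParameterError):
            rp.intersection_x(100.0, 0.5, 2.5, "lower")

    @given(s=st.floats(0.005, 0.2), cu=st.floats(0.1, 15.0), cl=st.floats(0.1, 4.9))
    @settings(max_examples=200, deadline=None)
    def test_boundary_consistent_from_both_sides(self, s, cu, cl):
        """The same x-coordinate is reached from the lower and the upper mean."""
        mu1 = 200.0
        ov = rp.BoundaryOverlap(cu, cl)
        mu2 = rp.next_mean(mu1, rp.ratio_from_overlap(s, ov))
        above = rp.intersection_x(mu1, s, cu, "upper")
        below = rp.intersection_x(mu2, s, cl, "lower")
        assert above == pytest.approx(below, rel=1e-9)


class TestIntersectionIdentity:
    def test_worked_two_category_example(self):
        """c_upper=2.5 with c_lower=2.2054 closes the identity for a 100/200 pair."""
        ov = rp.BoundaryOverlap(2.5, 2.2053810643242833)
        assert rp.intersection_identity_residual(ov, 100.0, 200.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_equal_overlaps_never_close_the_identity(self):
        ov = rp.BoundaryOverlap(3.0, 3.0)
        res = rp.intersection_identity_residual(ov, 100.0, 200.0)
        assert res == pytest.approx(-2.0 * math.log(2.0))
        assert res < 0

    def test_equal_means_rejected(self):
        with pytest.raises(rp.ParameterError):
            rp.intersection_identity_residual(rp.BoundaryOverlap(2.0, 2.0), 300.0, 300.0)


class TestSolveCLower:
    def test_worked_example_rounds_to_paperlike_value(self):
        c = rp.solve_c_lower(2.5, 2.0)
        assert c == pytest.approx(math.sqrt(6.25 - 2 * math.log(2)), abs=1e-12)
        assert round(c, 1) == 2.2

    def test_unit_ratio_algebraic_limit(self):
        assert rp.solve_c_lower(1.7, 1.0) == pytest.approx(1.7)

    def test_no_real_solution(self):
        with pytest.raises(rp.NoRealSolutionError):
            rp.solve_c_lower(1.0, 2.0)

    @given(c=st.floats(0.5, 20.0), r=st.floats(1.0, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_closes_exactly(self, c, r):
        try:
            cl = rp.solve_c_lower(c, r)
        except rp.NoRealSolutionError:
            assert c * c < 2 * math.log(r)
            return
        assert cl * cl + 2 * math.log(r) == pytest.approx(c * c, abs=1e-12)


class TestJointSolveOverlap:
    @pytest.mark.parametrize("key", sorted(JOINT_ORACLE))
    def test_matches_scanning_oracle(self, key):
        s, r = key
        cl, cu = JOINT_ORACLE[key]
        ov = rp.joint_solve_overlap(s, r)
        assert ov.c_lower_next == pytest.approx(cl, abs=1e-4)
        assert ov.c_upper == pytest.approx(cu, abs=1e-4)

    def test_oracle_values_are_current(self):
        """Recompute one frozen oracle entry by scanning, in-test."""
        roots = scan_joint_overlap(0.025, 2.0)
        assert len(roots) == 1  # the second algebraic root lies at c_l >= 1/s
        cl, cu = roots[0]
        assert (cl, cu) == pytest.approx(JOINT_ORACLE[(0.025, 2.0)], abs=1e-4)

    @pytest.mark.parametrize("s,r", [(0.025, 2.0), (0.025, 1.5), (0.1, 3.0)])
    def test_solution_satisfies_both_constraints(self, s, r):
        ov = rp.joint_solve_overlap(s, r)
        assert rp.ratio_from_overlap(s, ov) == pytest.approx(r, abs=1e-6)
        mu2 = rp.next_mean(300.0, r)
        assert rp.intersection_identity_residual(ov, 300.0, mu2) == pytest.approx(
            0.0, abs=1e-6
        )
        assert ov.c_lower_next < 1.0 / s

    def test_infeasible_parameters_raise(self):
        # verified by the scanning oracle: no root with positive c_upper in (0, 1/s)
        assert scan_joint_overlap(0.9, 1.05) == []
        with pytest.raises(rp.FeasibilityError):
            rp.joint_solve_overlap(0.9, 1.05)


class TestMeanDifferenceEquivalence:
    def test_direct_difference_equals_overlap_decomposition(self, rng):
        """mu2 - mu1 decomposes as s*c_l*mu2 + s*c_u*mu1 for 1000 random draws."""
        for _ in range(1000):
            s = rng.uniform(0.005, 0.2)
            cu = rng.uniform(0.05, 20.0)
            cl = rng.uniform(0.05, min(20.0, 0.99 / s))
            mu1 = rng.uniform(100.0, 500.0)
            ov = rp.BoundaryOverlap(cu, cl)
            mu2 = rp.next_mean(mu1, rp.ratio_from_overlap(s, ov))
            lhs = mu2 - mu1
            rhs = s * cl * mu2 + s * cu * mu1
            assert abs(lhs - rhs) <= 1e-9 * max(abs(lhs), 1.0)


class TestBuildCategorySystem:
    def test_constant_ratio_two(self):
        sys_ = rp.build_category_system(200.0, 0.025, 2.0)
        assert sys_.means == pytest.approx((200.0, 400.0, 800.0))
        assert sys_.K == 3
        assert sys_.sds == pytest.approx((5.0, 10.0, 20.0))
        assert sys_.weights == pytest.approx((1 / 3,) * 3)

    def test_first_mean_at_bound_gives_single_category(self):
        assert rp.build_category_system(1000.0, 0.025, 2.0).K == 1

    def test_finite_ratio_schedule(self):
        sys_ = rp.build_category_system(200.0, 0.025, [1.5, 1.5, 1.5])
        assert sys_.means == pytest.approx((200.0, 300.0, 450.0, 675.0))
        assert sys_.K == 4

    def test_overlap_schedule_equals_ratio_schedule(self):
        ov = rp.joint_solve_overlap(0.025, 2.0)
        assert rp.build_category_system(200.0, 0.025, ov).means == pytest.approx(
            rp.build_category_system(200.0, 0.025, 2.0).means, rel=1e-9
        )

    def test_mu1_out_of_bounds_rejected(self):
        with pytest.raises(rp.ParameterError):
            rp.build_category_system(50.0, 0.025, 2.0)

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(rp.FeasibilityError):
            rp.build_category_system(200.0, 0.025, rp.BoundaryOverlap(2.0, 45.0))

    @pytest.mark.parametrize(
        "mu1,sched,expected_K", [(200.0, 2.0, 3), (200.0, 10.0, 1), (500.0, 1.5, 2)]
    )
    def test_max_categories(self, mu1, sched, expected_K):
        assert rp.max_categories(mu1, sched) == expected_K


class TestEq8EnforcementEverywhere:
    """Overlaps with c_lower_next >= 1/s must be rejected, never clamped."""

    @given(s=st.floats(0.01, 0.5), excess=st.floats(0.0, 50.0))
    @settings(max_examples=300, deadline=None)
    def test_fuzzed_infeasible_overlaps_always_raise(self, s, excess):
        ov = rp.BoundaryOverlap(c_upper=1.0, c_lower_next=1.0 / s + excess)
        with pytest.raises(rp.FeasibilityError):
            rp.ratio_from_overlap(s, ov)
        with pytest.raises(rp.FeasibilityError):
            rp.build_category_system(250.0, s, ov, rp.ScalarTimingParams(s=s))


class TestSerialization:
    def test_json_round_trip_and_derived_sds(self, default_system):
        text = default_system.to_json()
        obj = json.loads(text)
        assert set(obj) == {"s", "means_ms", "weights", "mu_min_ms", "mu_max_ms"}
        back = rp.CategorySystem.from_json(text)
        assert back == default_system
        assert back.sds == pytest.approx((5.0, 10.0, 20.0))

    def test_invalid_system_rejected(self):
        with pytest.raises(rp.ParameterError):
            rp.CategorySystem(means=(400.0, 200.0))
        with pytest.raises(rp.ParameterError):
            rp.CategorySystem(means=(200.0, 1200.0))
        with pytest.raises(rp.ParameterError):
            rp.CategorySystem(means=(200.0, 400.0), weights=(0.6, 0.6))
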