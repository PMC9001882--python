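"""Objective functions, constraints and design evaluations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathtune.models import MERGING
from pathtune.objectives import (
    MERGING_DECISION,
    NARINGENIN_DECISION,
    clip_binary,
    evaluate_constraints,
    evaluate_merging,
    evaluate_naringenin,
    j1_titer_error,
    j2_production_loss,
    j3_count_oscillations,
    knar_conversion,
)
from pathtune.simulate import Trajectory
from pathtune.units import micromolar_to_molecules


def brute_force_crossings(series: np.ndarray) -> int:
    """Independent mean-crossing counter: strict sign changes of s - mean."""
    d = np.asarray(series, float) - np.mean(series)
    signs = np.sign(d)
    crossings = 0
    prev = 0.0
    for s in signs:
        if s == 0.0:
            continue
        if prev != 0.0 and s != prev:
            crossings += 1
        prev = s
    return crossings


class TestJ1:
    def test_zero_at_exact_target(self):
        assert j1_titer_error(P_T=800.0, K=1.0 / 800.0, target=1.0) == 0.0

    def test_direct_arithmetic(self):
        assert j1_titer_error(P_T=800.0, K=1e-3, target=1.0) == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None)
    @given(
        P=st.floats(min_value=0, max_value=1e9),
        K=st.floats(min_value=1e-9, max_value=1e3),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_invariant_under_rescaling(self, P, K, c):
        # (K, P) -> (cK, P/c) leaves the titer, hence J1, unchanged
        a = j1_titer_error(P, K, target=1.0)
        b = j1_titer_error(P / c, c * K, target=1.0)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


class TestJ2:
    def test_perfect_adaptation_zero(self):
        assert j2_production_loss(100.0, 100.0) == 0.0

    def test_total_loss_one(self):
        assert j2_production_loss(100.0, 0.0) == 1.0

    def test_direct_arithmetic_and_sign(self):
        assert j2_production_loss(100.0, 80.0) == pytest.approx(0.2)
        assert j2_production_loss(100.0, 120.0) == pytest.approx(-0.2)

    def test_undefined_for_zero_baseline(self):
        with pytest.raises(ValueError):
            j2_production_loss(0.0, 10.0)


class TestClipBinaryAndJ3:
    def test_constant_series_all_ties(self):
        X = clip_binary([3.0, 3.0, 3.0])
        assert np.all(X == 0.5)
        assert j3_count_oscillations([3.0, 3.0, 3.0]) == 0.0

    def test_alternating_series(self):
        X = clip_binary([0.0, 2.0, 0.0, 2.0])
        assert np.array_equal(X, [1.0, 0.0, 1.0, 0.0])

    def test_single_monotone_crossing(self):
        assert j3_count_oscillations([0.0, 0.0, 2.0, 2.0]) == 0.5

    @pytest.mark.parametrize("n_periods", [1, 2, 3])
    def test_sinusoid_counts_periods(self, n_periods):
        t = np.linspace(0.0, 1.0, 40 * n_periods, endpoint=False)
        s = np.sin(2 * np.pi * n_periods * t + 0.3)
        assert j3_count_oscillations(s) == pytest.approx(float(n_periods))

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(2, 60)
            s = rng.normal(size=n)
            assert j3_count_oscillations(s) == brute_force_crossings(s) / 2.0

    def test_multiple_of_half(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = rng.normal(size=30)
            assert (2 * j3_count_oscillations(s)) == int(2 * j3_count_oscillations(s))


class TestKnarConversion:
    def test_substitution(self):
        assert knar_conversion(x_T=6.02214076e23, mw=272.25, Vext=1.0) == pytest.approx(272.25)

    def test_linear_in_cells(self):
        assert knar_conversion(2e12) == pytest.approx(2 * knar_conversion(1e12))

    def test_volume_division(self):
        assert knar_conversion(1e12, Vext=2.0) == pytest.approx(knar_conversion(1e12) / 2.0)


def _sigma_traj(sigma_uM, asigma_uM, n=50):
    times = np.linspace(0.0, 1000.0, n)
    sigma = np.full(n, micromolar_to_molecules(sigma_uM))
    asigma = np.full(n, micromolar_to_molecules(asigma_uM))
    return Trajectory(times, np.column_stack([sigma, asigma]), ("sigma", "asigma"))


class TestConstraints:
    def test_feasible_case(self):
        rep = evaluate_constraints(_sigma_traj(10.0, 1.0))
        assert rep.feasible and rep.violation == 0.0

    def test_sigma_floor_shortfall(self):
        rep = evaluate_constraints(_sigma_traj(4.0, 1.0))
        assert not rep.feasible
        assert rep.per_constraint["sigma_floor_uM"] == pytest.approx(0.5, abs=1e-9)

    def test_dominance_boundary_is_feasible(self):
        rep = evaluate_constraints(_sigma_traj(6.0, 6.0))
        assert rep.per_constraint["sigma_dominance_uM"] == 0.0
        assert rep.feasible


class TestEvaluateMerging:
    @pytest.fixture(scope="class")
    def midpoint_eval(self, merging_params, short_merging_protocol):
        theta = (np.array(MERGING_DECISION.lower) + np.array(MERGING_DECISION.upper)) / 2
        return theta, evaluate_merging(theta, merging_params, short_merging_protocol)

    def test_midpoint_is_finite_with_partial_loss(self, midpoint_eval):
        _, (objs, diag) = midpoint_eval
        assert np.isfinite(objs.J1) and np.isfinite(objs.J2)
        assert objs.J2 < 1.0
        assert "E_max_uM" in diag

    def test_deterministic_replay(self, merging_params, short_merging_protocol, midpoint_eval):
        theta, (objs, _) = midpoint_eval
        objs2, _ = evaluate_merging(theta, merging_params, short_merging_protocol)
        assert objs2.as_tuple() == objs.as_tuple()

    def test_self_consistent_target_zeroes_j1(
        self, merging_params, short_merging_protocol, midpoint_eval
    ):
        theta, (objs, diag) = midpoint_eval
        objs2, _ = evaluate_merging(
            theta, merging_params, short_merging_protocol, target=diag["titer"]
        )
        assert objs2.J1 == pytest.approx(0.0, abs=1e-12)

    def test_out_of_bounds_rejected(self, merging_params, short_merging_protocol):
        theta = np.array(MERGING_DECISION.upper) * 1.5
        with pytest.raises(ValueError):
            evaluate_merging(theta, merging_params, short_merging_protocol)


class TestEvaluateNaringenin:
    @pytest.fixture(scope="class")
    def fast_protocol(self, naringenin_protocol):
        return dataclasses.replace(naringenin_protocol, n_points=300)

    def test_copy_numbers_rounded_and_replay(self, naringenin_params, fast_protocol):
        theta = np.array([10.0, 5.4, 5.0, 5.0, 1.0, 300.0, 0.0116])
        objs, rep, diag = evaluate_naringenin(theta, naringenin_params, fast_protocol)
        theta_rounded = theta.copy()
        theta_rounded[1] = 5.0
        objs2, rep2, _ = evaluate_naringenin(theta_rounded, naringenin_params, fast_protocol)
        assert objs.as_tuple() == objs2.as_tuple()
        assert rep.violation == rep2.violation

    def test_j3_is_multiple_of_half_and_finite(self, naringenin_params, fast_protocol):
        theta = np.array([10.0, 5.0, 5.0, 5.0, 1.0, 300.0, 0.0116])
        objs, rep, diag = evaluate_naringenin(theta, naringenin_params, fast_protocol)
        assert objs.J3 >= 0.0
        assert 2 * objs.J3 == int(2 * objs.J3)
        assert diag["titer_g_per_L"] > 0.0
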