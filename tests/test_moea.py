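"""Optimizer building blocks: dominance, DE operators, pruning, archives."""

import numpy as np
import pytest

from pathtune.moea import (
    Archive,
    Individual,
    MOEAConfig,
    constrained_compare,
    de_trial,
    dominates,
    hypervolume,
    run_moea,
    sector_index,
    spherical_prune,
)
from oracles import brute_force_prune, random_nondominated
from pathtune.objectives import DecisionSpace


class ToyProblem:
    """min (theta^2, (theta-1)^2): analytic front J2 = (1 - sqrt(J1))^2."""

    objective_names = ("J1", "J2")
    bounds = DecisionSpace(names=("theta",), lower=(-1.0,), upper=(2.0,), integer=(False,))

    def evaluate(self, theta):
        t = float(theta[0])
        return (t * t, (t - 1.0) ** 2), 0.0


class ScalarProblem:
    """Degenerate bi-objective with J2 constant: reduces to scalar DE."""

    objective_names = ("J1", "J2")
    bounds = DecisionSpace(names=("theta",), lower=(-1.0,), upper=(2.0,), integer=(False,))

    def evaluate(self, theta):
        return (float(theta[0]) ** 2, 0.0), 0.0


class TestDominates:
    def test_strict_domination(self):
        assert dominates((1, 1), (2, 2))

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates((1, 1), (1, 1))

    def test_incomparable_pair(self):
        assert not dominates((1, 3), (3, 1))
        assert not dominates((3, 1), (1, 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


class TestConstrainedCompare:
    def _ind(self, objs, viol):
        return Individual(np.zeros(1), objs, viol)

    def test_feasible_beats_infeasible(self):
        assert constrained_compare(self._ind((9, 9), 0.0), self._ind((1, 1), 0.5)) == -1

    def test_infeasibles_compared_by_violation(self):
        assert constrained_compare(self._ind((1, 1), 0.2), self._ind((1, 1), 0.5)) == -1

    def test_feasible_incomparable_no_preference(self):
        assert constrained_compare(self._ind((1, 3), 0.0), self._ind((3, 1), 0.0)) == 0


class TestDeTrial:
    bounds = DecisionSpace(
        names=("a", "b", "cn"),
        lower=(0.0, 0.0, 1.0),
        upper=(10.0, 10.0, 15.0),
        integer=(False, False, True),
    )

    def _population(self, rng):
        pop = rng.random((8, 3)) * [10.0, 10.0, 14.0] + [0, 0, 1]
        pop[:, 2] = np.round(pop[:, 2])
        return pop

    def test_formula_collapse_f0_cr1(self):
        rng = np.random.default_rng(0)
        pop = self._population(rng)
        rng2 = np.random.default_rng(1)
        trial = de_trial(pop, 0, F=0.0, CR=1.0, rng=rng2, bounds=self.bounds)
        # with F=0 and full crossover the trial is exactly some population member
        assert any(np.allclose(trial, pop[j]) for j in range(1, len(pop)))

    def test_respects_bounds_and_integrality(self):
        rng = np.random.default_rng(3)
        pop = self._population(rng)
        for i in range(8):
            t = de_trial(pop, i, F=0.9, CR=0.9, rng=rng, bounds=self.bounds)
            assert self.bounds.contains(t)
            assert t[2] == round(t[2])

    def test_seeded_determinism(self):
        pop = self._population(np.random.default_rng(0))
        t1 = de_trial(pop, 2, 0.8, 0.9, np.random.default_rng(7), self.bounds)
        t2 = de_trial(pop, 2, 0.8, 0.9, np.random.default_rng(7), self.bounds)
        assert np.array_equal(t1, t2)


class TestSphericalPrune:
    def test_single_member_unchanged(self):
        m = [Individual(np.zeros(1), (1.0, 2.0), 0.0, eval_id=0)]
        assert spherical_prune(m, arcs=10) == m

    def test_two_members_distinct_sectors_kept(self):
        ms = [
            Individual(np.zeros(1), (0.0, 1.0), 0.0, eval_id=0),
            Individual(np.zeros(1), (1.0, 0.0), 0.0, eval_id=1),
        ]
        assert len(spherical_prune(ms, arcs=10)) == 2

    @pytest.mark.parametrize("m_obj", [2, 3])
    def test_matches_brute_force_oracle(self, m_obj):
        rng = np.random.default_rng(11)
        for _ in range(20):
            members = random_nondominated(rng, 40, m_obj)
            kept = spherical_prune(members, arcs=10)
            oracle = brute_force_prune(members, arcs=10)
            assert [m.eval_id for m in kept] == [m.eval_id for m in oracle]


class TestArchive:
    def _ind(self, objs, viol=0.0, eid=0):
        return Individual(np.zeros(1), objs, viol, eval_id=eid)

    def test_dominated_candidates_rejected(self):
        a = Archive()
        a.add(self._ind((1.0, 1.0), eid=0))
        assert not a.add(self._ind((2.0, 2.0), eid=1))
        assert len(a) == 1

    def test_dominating_candidate_sweeps(self):
        a = Archive()
        a.add(self._ind((1.0, 3.0), eid=0))
        a.add(self._ind((3.0, 1.0), eid=1))
        a.add(self._ind((0.5, 0.5), eid=2))
        assert len(a) == 1 and a.members[0].eval_id == 2

    def test_feasible_displaces_infeasible(self):
        a = Archive()
        a.add(self._ind((1.0, 1.0), viol=0.7, eid=0))
        a.add(self._ind((1.0, 1.0), viol=0.2, eid=1))
        assert len(a) == 1 and a.members[0].violation == 0.2
        a.add(self._ind((9.0, 9.0), viol=0.0, eid=2))
        assert len(a) == 1 and a.members[0].feasible

    def test_capacity_triggers_pruning(self):
        a = Archive(capacity=10, arcs=5)
        rng = np.random.default_rng(0)
        for i, m in enumerate(random_nondominated(rng, 30, 2)):
            a.add(m)
        assert len(a) <= 10


class TestHypervolume:
    def test_single_point_rectangle(self):
        assert hypervolume([(1.0, 1.0)], (3.0, 2.0)) == pytest.approx(2.0)

    def test_dominated_point_adds_nothing(self):
        hv1 = hypervolume([(1.0, 1.0)], (3.0, 3.0))
        hv2 = hypervolume([(1.0, 1.0), (2.0, 2.0)], (3.0, 3.0))
        assert hv1 == pytest.approx(hv2)

    def test_3d_matches_inclusion_exclusion(self):
        pts = [(1.0, 2.0, 0.5), (0.5, 2.5, 1.0), (2.0, 0.5, 1.5)]
        ref = (3.0, 3.0, 2.0)
        # inclusion–exclusion over the three boxes
        def vol(p):
            return np.prod([r - v for v, r in zip(p, ref)])

        def inter(*ps):
            m = np.max(ps, axis=0)
            if np.any(m >= ref):
                return 0.0
            return vol(m)

        expected = (
            sum(vol(p) for p in pts)
            - inter(pts[0], pts[1]) - inter(pts[0], pts[2]) - inter(pts[1], pts[2])
            + inter(*pts)
        )
        assert hypervolume(pts, ref) == pytest.approx(float(expected))


class TestRunMoea:
    def test_toy_front_recovered(self):
        cfg = MOEAConfig(
            population_size=40, generations=49, max_evaluations=2000, seed=5,
            hv_ref=(2.0, 2.0),
        )
        res = run_moea(ToyProblem(), cfg)
        J = res.archive.objective_matrix()
        dev = np.abs(J[:, 1] - (1.0 - np.sqrt(J[:, 0])) ** 2)
        assert dev.max() < 0.01
        th = res.archive.thetas().ravel()
        assert th.min() >= -0.02 and th.max() <= 1.02

    def test_scalar_degenerate_converges(self):
        cfg = MOEAConfig(population_size=20, generations=40, seed=2)
        res = run_moea(ScalarProblem(), cfg)
        assert len(res.archive) == 1
        assert abs(res.archive.members[0].theta[0]) < 0.01

    def test_seeded_rerun_identical(self):
        cfg = MOEAConfig(population_size=20, generations=10, seed=9)
        r1 = run_moea(ToyProblem(), cfg)
        r2 = run_moea(ToyProblem(), cfg)
        assert np.array_equal(r1.archive.objective_matrix(), r2.archive.objective_matrix())
        assert r1.log.equals(r2.log)

    def test_objective_caps_exclude_nonpertinent_solutions(self):
        cfg = MOEAConfig(
            population_size=20, generations=15, seed=3, objective_caps=(0.5, np.inf)
        )
        res = run_moea(ToyProblem(), cfg)
        J = res.archive.objective_matrix()
        assert J[:, 0].max() < 0.5
        # capped evaluations are still logged
        assert (res.log["J1"] >= 0.5).any()

    def test_budget_validation(self):
        cfg = MOEAConfig(population_size=20, generations=10, max_evaluations=10, seed=0)
        with pytest.raises(ValueError):
            run_moea(ToyProblem(), cfg)

    def test_all_thetas_logged_within_bounds(self):
        cfg = MOEAConfig(population_size=10, generations=5, seed=4)
        res = run_moea(ToyProblem(), cfg)
        th = res.log["theta_theta"].to_numpy()
        assert th.min() >= -1.0 and th.max() <= 2.0

    def test_grid_enumeration_dominance(self):
        # after a generous budget, exhaustive grid search cannot beat the
        # archive: no grid point dominates any archive member
        cfg = MOEAConfig(population_size=20, generations=30, seed=8)
        res = run_moea(ToyProblem(), cfg)
        archive_objs = res.archive.objective_matrix()
        for t in np.linspace(-1.0, 2.0, 61):
            g = np.array([t * t, (t - 1.0) ** 2])
            beaten = np.all(g <= archive_objs - 1e-9, axis=1)
            assert not beaten.any(), f"grid point {g} dominates an archive member"
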