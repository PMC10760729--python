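import itertools
import math

import numpy as np
import pytest

from conftest import line_od
from hospisite import (
    MaxCoveringLocation,
    PMedian,
    flag_inaccessible,
    generate_city,
    mc_p_median_optimize,
    mclp_solve,
    od_matrix,
    p_median_exact,
    p_median_heuristic,
)
from hospisite.allocation import InstanceTooLargeError, _pmedian_objective


def brute_force_pmedian(times, weights, p, cutoff):
    """Independent oracle: re-derived objective over all subsets."""
    n_f = times.shape[1]
    best = (math.inf, None)
    for subset in itertools.combinations(range(n_f), p):
        total = 0.0
        for i, w in enumerate(weights):
            d = min(times[i, j] for j in subset)
            if math.isfinite(d) and (cutoff is None or d <= cutoff):
                total += w * d
        if total < best[0] - 1e-12:
            best = (total, subset)
    return best


def brute_force_mclp(times, weights, p, cutoff):
    best = (-1.0, None)
    for subset in itertools.combinations(range(times.shape[1]), p):
        covered = sum(
            w for i, w in enumerate(weights)
            if min(times[i, j] for j in subset) <= cutoff
        )
        if covered > best[0] + 1e-12:
            best = (covered, subset)
    return best


def random_instance(rng, n_d=12, n_f=5):
    times = rng.uniform(0.1, 4.0, size=(n_d, n_f))
    weights = rng.integers(1, 50, size=n_d).astype(float)
    return times, weights


class TestPMedianExact:
    def test_line_instance_p1(self):
        od = line_od([0, 1, 2, 10], [1, 10])
        alloc = p_median_exact(od, [1, 1, 1, 1], p=1)
        assert alloc.chosen_sites == (0,)  # the site at position 1
        assert alloc.objective == pytest.approx(11.0)

    def test_line_instance_p2(self):
        od = line_od([0, 1, 2, 10], [1, 10])
        alloc = p_median_exact(od, [1, 1, 1, 1], p=2)
        assert alloc.objective == pytest.approx(2.0)
        assert alloc.chosen_sites == (0, 1)

    def test_full_opening_assigns_everyone_to_nearest(self):
        rng = np.random.default_rng(5)
        times, weights = random_instance(rng)
        od = line_od(range(12), range(5))
        od.times = times
        alloc = p_median_exact(od, weights, p=5)
        expected = float(np.sum(weights * times.min(axis=1)))
        assert alloc.objective == pytest.approx(expected)
        for i, d in enumerate(od.demand_ids):
            assert alloc.assignment[d] == int(np.argmin(times[i]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(25):
            times, weights = random_instance(rng, n_d=10, n_f=6)
            od = line_od(range(10), range(6))
            od.times = times
            p = int(rng.integers(1, 6))
            cutoff = float(rng.uniform(0.5, 3.0)) if trial % 2 else None
            alloc = p_median_exact(od, weights, p=p, cutoff_h=cutoff)
            obj, subset = brute_force_pmedian(times, weights, p, cutoff)
            assert alloc.objective == pytest.approx(obj)

    def test_objective_monotone_nonincreasing_in_p(self):
        rng = np.random.default_rng(3)
        times, weights = random_instance(rng, n_d=15, n_f=6)
        od = line_od(range(15), range(6))
        od.times = times
        objs = [p_median_exact(od, weights, p=p).objective for p in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_p_out_of_range_and_size_guard(self):
        od = line_od([0, 1], [0, 1])
        with pytest.raises(ValueError):
            p_median_exact(od, [1, 1], p=0)
        with pytest.raises(ValueError):
            p_median_exact(od, [1, 1], p=3)
        est = PMedian(p=1, method="exact", max_enumeration=1)
        with pytest.raises(InstanceTooLargeError):
            est.fit(od.times, [1, 1])

    def test_assignment_reproduces_objective(self):
        rng = np.random.default_rng(8)
        times, weights = random_instance(rng)
        od = line_od(range(12), range(5))
        od.times = times
        alloc = p_median_exact(od, dict(zip(od.demand_ids, weights)), p=2,
                               cutoff_h=2.0)
        w = dict(zip(od.demand_ids, weights))
        assert alloc.recompute_objective(od, w) == pytest.approx(
            alloc.objective, abs=1e-9)


class TestPMedianHeuristic:
    def test_equals_exact_on_most_seeded_instances_never_below(self):
        rng = np.random.default_rng(42)
        hits = 0
        for trial in range(100):
            times, weights = random_instance(rng, n_d=12, n_f=6)
            od = line_od(range(12), range(6))
            od.times = times
            p = int(rng.integers(1, 6))
            exact = p_median_exact(od, weights, p=p)
            heur = p_median_heuristic(od, weights, p=p, seed=trial, restarts=5)
            assert heur.objective >= exact.objective - 1e-9
            hits += abs(heur.objective - exact.objective) < 1e-9
        assert hits >= 95

    def test_p_equals_n_matches_exact(self):
        od = line_od([0, 2, 5, 9], [1, 4, 8])
        exact = p_median_exact(od, [1, 2, 3, 4], p=3)
        heur = p_median_heuristic(od, [1, 2, 3, 4], p=3, seed=0)
        assert heur.objective == pytest.approx(exact.objective)
        assert heur.chosen_sites == exact.chosen_sites

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        times, weights = random_instance(rng, n_d=20, n_f=8)
        od = line_od(range(20), range(8))
        od.times = times
        a = p_median_heuristic(od, weights, p=3, seed=9)
        b = p_median_heuristic(od, weights, p=3, seed=9)
        assert a.chosen_sites == b.chosen_sites
        assert a.objective == b.objective


class TestMCLP:
    def test_full_coverage_when_cutoff_exceeds_all(self):
        od = line_od([0, 1, 2], [1])
        alloc = mclp_solve(od, [5, 3, 2], p=1, cutoff_h=10.0)
        assert alloc.objective == pytest.approx(10.0)

    def test_line_instance_p1_prefers_heavy_demand(self):
        od = line_od([0, 2, 4], [0, 3])
        alloc = mclp_solve(od, [5, 1, 1], p=1, cutoff_h=1.0)
        assert alloc.chosen_sites == (0,)
        assert alloc.objective == pytest.approx(5.0)

    def test_line_instance_p2_covers_everything(self):
        od = line_od([0, 2, 4], [0, 3])
        alloc = mclp_solve(od, [5, 1, 1], p=2, cutoff_h=1.0)
        assert alloc.objective == pytest.approx(7.0)

    def test_missing_cutoff_rejected(self):
        od = line_od([0, 1], [0])
        with pytest.raises(ValueError):
            mclp_solve(od, [1, 1], p=1, cutoff_h=None)

    def test_ilp_matches_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            times, weights = random_instance(rng, n_d=15, n_f=7)
            p = int(rng.integers(1, 7))
            cutoff = float(rng.uniform(0.5, 2.5))
            enum_w, _ = brute_force_mclp(times, weights, p, cutoff)
            est = MaxCoveringLocation(p=p, cutoff_h=cutoff, method="exact",
                                      max_enumeration=0)  # force the ILP path
            est.fit(times, weights)
            assert est.objective_ == pytest.approx(enum_w)

    def test_greedy_respects_submodular_bound(self):
        rng = np.random.default_rng(77)
        bound = 1 - 1 / math.e
        for _ in range(50):
            times, weights = random_instance(rng, n_d=15, n_f=7)
            p = int(rng.integers(1, 7))
            cutoff = float(rng.uniform(0.3, 2.5))
            od = line_od(range(15), range(7))
            od.times = times
            exact = mclp_solve(od, weights, p=p, cutoff_h=cutoff)
            greedy = mclp_solve(od, weights, p=p, cutoff_h=cutoff, method="greedy")
            assert greedy.objective >= bound * exact.objective - 1e-9
            assert greedy.objective <= exact.objective + 1e-9

    def test_covered_weight_monotone_in_p_and_cutoff(self):
        rng = np.random.default_rng(21)
        times, weights = random_instance(rng, n_d=15, n_f=6)
        od = line_od(range(15), range(6))
        od.times = times
        by_p = [mclp_solve(od, weights, p=p, cutoff_h=1.0).objective
                for p in range(1, 7)]
        assert all(a <= b + 1e-9 for a, b in zip(by_p, by_p[1:]))
        by_cut = [mclp_solve(od, weights, p=2, cutoff_h=c).objective
                  for c in (0.5, 1.0, 1.5, 2.0, 3.0)]
        assert all(a <= b + 1e-9 for a, b in zip(by_cut, by_cut[1:]))


class TestFlagInaccessible:
    def test_colocated_demands_not_flagged(self):
        od = line_od([0, 3], [0, 3])
        assert flag_inaccessible(od, 0.5) == set()

    def test_disconnected_demand_flagged(self):
        od = line_od([0, 1], [0])
        od.times[1, 0] = math.inf
        assert flag_inaccessible(od, 100.0) == {1}

    def test_engineered_city_flags_exactly_the_remote_districts(self, city_remote):
        od = od_matrix(city_remote.network, city_remote.demands,
                       city_remote.facilities)
        flagged = flag_inaccessible(od, 6.0)
        assert len(flagged) == 16
        remote_ids = {d.demand_id for d in city_remote.demands[-16:]}
        assert flagged == remote_ids


class TestMCPMedian:
    def test_noop_when_everything_reachable(self):
        od = line_od([0, 1, 2, 3], [0, 3])
        opt = mc_p_median_optimize(od, [1, 1, 1, 1], p=2, cutoff_h=5.0)
        assert opt.inaccessible == frozenset()
        assert opt.final.assignment == opt.p_median.assignment
        assert opt.audit_log == []

    def test_engineered_city_allocates_94_of_110(self, city_remote):
        od = od_matrix(city_remote.network, city_remote.demands,
                       city_remote.facilities)
        w = {d.demand_id: float(d.population) for d in city_remote.demands}
        opt = mc_p_median_optimize(od, w, p=5, cutoff_h=6.0)
        assert len(opt.inaccessible) == 16
        assert opt.final.allocated_count == 94
        assert opt.final.allocated_count + len(opt.inaccessible) == 110

    def test_final_coverage_dominates_stage1(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            times, weights = random_instance(rng, n_d=20, n_f=6)
            od = line_od(range(20), range(6))
            od.times = times
            cutoff = float(rng.uniform(0.5, 2.0))
            p = int(rng.integers(1, 6))
            opt = mc_p_median_optimize(od, weights, p=p, cutoff_h=cutoff)
            w = dict(zip(od.demand_ids, weights))
            assert (opt.final.covered_weight(w)
                    >= opt.p_median.covered_weight(w) - 1e-9)

    def test_audit_log_records_removals(self, city_remote):
        od = od_matrix(city_remote.network, city_remote.demands,
                       city_remote.facilities)
        w = {d.demand_id: float(d.population) for d in city_remote.demands}
        opt = mc_p_median_optimize(od, w, p=5, cutoff_h=6.0)
        removed = {e["demand_id"] for e in opt.audit_log
                   if e["event"] == "removed"}
        assert removed == set(opt.inaccessible)

    def test_assigned_demands_respect_cutoff(self):
        rng = np.random.default_rng(10)
        times, weights = random_instance(rng, n_d=20, n_f=6)
        od = line_od(range(20), range(6))
        od.times = times
        opt = mc_p_median_optimize(od, weights, p=2, cutoff_h=1.0)
        for d, f in opt.final.assignment.items():
            if f is not None:
                assert od.times[d, f] <= 1.0 + 1e-12
                assert f in opt.final.chosen_sites
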