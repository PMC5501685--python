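import numpy as np
import pytest

import coregrn as c
from coregrn.network import NetworkStructure
from coregrn.selection import (
    PruningTrace,
    SelectionCriterion,
    chi2_assess,
    consensus_rank,
    stop_index_from_increases,
)


def _trace(universe, order, stop=None, costs=None, seed=None):
    order = tuple(order)
    return PruningTrace(
        edge_universe=tuple(universe),
        removal_order=order,
        cost_at_step=np.arange(len(order), dtype=float) if costs is None else np.asarray(costs, float),
        initial_cost=0.0,
        stop_index=len(order) if stop is None else stop,
        final_structure=NetworkStructure(("A",)),
        seed=seed,
    )


class TestStopRule:
    def test_first_increase_over_threshold_stops(self):
        # increases (0.01 s, 0.02 s, 0.07 s) with c = 0.05: stop before the third
        s = 10.0
        increases = [0.01 * s, 0.02 * s, 0.07 * s]
        assert stop_index_from_increases(increases, s, 0.05) == 2

    def test_no_trip_accepts_all(self):
        assert stop_index_from_increases([0.0, -1.0, 0.01], 1.0, 0.05) == 3

    def test_immediate_trip(self):
        assert stop_index_from_increases([5.0], 1.0, 0.05) == 0


class TestChi2Assess:
    @pytest.mark.parametrize(
        "df,expected",
        [(72, 92.8), (6, 12.6), (48, 65.2)],
    )
    def test_critical_values_at_alpha_005(self, df, expected):
        crit, _ = chi2_assess(0.0, df, 0.05)
        assert crit == pytest.approx(expected, abs=0.05)

    def test_rejection_flag(self):
        crit, rejected = chi2_assess(15.0, 72, 0.05)
        assert not rejected
        _, rejected = chi2_assess(95.0, 72, 0.05)
        assert rejected

    def test_agrees_with_bisection_on_incomplete_gamma(self):
        """Independent numeric oracle: invert the chi2 CDF by bisection on
        the regularized incomplete gamma function."""
        from scipy.special import gammainc

        for df in (6, 48, 72):
            lo, hi = 0.0, 500.0
            for _ in range(80):
                mid = (lo + hi) / 2
                if gammainc(df / 2, mid / 2) < 0.95:
                    lo = mid
                else:
                    hi = mid
            crit, _ = chi2_assess(0.0, df, 0.05)
            assert crit == pytest.approx((lo + hi) / 2, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_assess(1.0, 0, 0.05)
        with pytest.raises(ValueError):
            chi2_assess(1.0, 5, 1.5)


class TestConsensusRank:
    UNIVERSE = [("A", "B"), ("A", "C"), ("B", "C")]

    def test_median_rank_and_threshold_inclusion(self):
        # one edge with ranks (5, 50, 60): median 50 > threshold 40 -> included
        e = ("A", "B")
        universe = [e] + [("A", f"G{i:02d}") for i in range(59)]
        traces = []
        for pos in (5, 50, 60):
            rest = [x for x in universe if x != e]
            order = rest[: pos - 1] + [e] + rest[pos - 1:]
            traces.append(_trace(universe, order))
        table = consensus_rank(traces, rank_threshold=40)
        assert table.loc["A->B", "median_rank"] == 50
        assert bool(table.loc["A->B", "included"])

    def test_small_example_included_and_excluded(self):
        t1 = _trace(self.UNIVERSE, [("A", "B"), ("A", "C"), ("B", "C")])
        t2 = _trace(self.UNIVERSE, [("A", "C"), ("A", "B"), ("B", "C")])
        t3 = _trace(self.UNIVERSE, [("A", "B"), ("A", "C"), ("B", "C")])
        table = consensus_rank([t1, t2, t3], rank_threshold=2)
        assert table.loc["B->C", "median_rank"] == 3
        assert bool(table.loc["B->C", "included"])
        assert not bool(table.loc["A->B", "included"])

    def test_identical_traces_reproduce_single_order(self):
        t = _trace(self.UNIVERSE, [("B", "C"), ("A", "B"), ("A", "C")])
        table = consensus_rank([t, t, t], rank_threshold=10)
        assert table.loc["B->C", "median_rank"] == 1
        assert table.loc["A->C", "median_rank"] == 3

    def test_never_removed_edge_gets_sentinel_rank(self):
        t1 = _trace(self.UNIVERSE, [("A", "B")])
        t2 = _trace(self.UNIVERSE, [("A", "B")])
        table = consensus_rank([t1, t2], rank_threshold=3)
        assert table.loc["B->C", "median_rank"] == len(self.UNIVERSE) + 1
        assert bool(table.loc["B->C", "included"])

    def test_permutation_invariance(self):
        t1 = _trace(self.UNIVERSE, [("A", "B"), ("B", "C"), ("A", "C")])
        t2 = _trace(self.UNIVERSE, [("B", "C"), ("A", "C"), ("A", "B")])
        t3 = _trace(self.UNIVERSE, [("A", "C"), ("A", "B"), ("B", "C")])
        a = consensus_rank([t1, t2, t3], 2)
        b = consensus_rank([t3, t1, t2], 2)
        assert a.equals(b)

    def test_mismatched_universes_rejected(self):
        t1 = _trace(self.UNIVERSE, [("A", "B")])
        t2 = _trace([("A", "B")], [("A", "B")])
        with pytest.raises(ValueError, match="different edge universes"):
            consensus_rank([t1, t2], 2)

    def test_needs_at_least_two_traces(self):
        t1 = _trace(self.UNIVERSE, [("A", "B")])
        with pytest.raises(ValueError, match=">= 2"):
            consensus_rank([t1], 2)


class TestBootstrapSensitivity:
    @pytest.fixture(scope="class")
    def evaluator(self, tiny_truth, tiny_data):
        from coregrn.objective import CostEvaluator

        ts, kd = tiny_data
        return CostEvaluator(tiny_truth.structure.core_subsystem(), ts, kd)

    def test_all_ones_weights_reproduce_unweighted_pruning(self, evaluator):
        from coregrn.data import BootstrapWeights
        from coregrn.selection import backward_eliminate

        kwargs = dict(seed=4, initial_budget=2000, refit_budget=300,
                      popsize=20, refit_polish_iters=40)
        plain, _ = backward_eliminate(evaluator, SelectionCriterion(), **kwargs)
        ones = BootstrapWeights.ones(evaluator.ts, evaluator.kd)
        weighted, _ = backward_eliminate(
            evaluator.with_weights(ones), SelectionCriterion(), **kwargs
        )
        assert plain.removal_order == weighted.removal_order
        np.testing.assert_array_equal(plain.cost_at_step, weighted.cost_at_step)

    def test_replicates_are_seeded_and_flagged(self, evaluator):
        from coregrn.selection import bootstrap_sensitivity, rank_variability

        out = bootstrap_sensitivity(
            evaluator, n_boot=2, seed=9,
            initial_budget=1500, refit_budget=300, popsize=20,
            refit_polish_iters=40,
        )
        assert len(out) == 2
        assert all(o["error"] is None for o in out)
        traces = [o["trace"] for o in out]
        assert all(t.removal_order for t in traces)
        assert rank_variability(traces) >= 0.0
        # weights differ between replicates
        assert not np.array_equal(out[0]["weights"].tau_timeseries,
                                  out[1]["weights"].tau_timeseries)

    def test_zero_weight_point_is_absent_from_cost(self, evaluator, rng):
        """tau = 0 annihilates a point: oracle check by explicit residual."""
        from coregrn.data import BootstrapWeights

        theta = rng.uniform(0.5, 2.0, evaluator.n_params)
        tau = np.ones_like(evaluator.ts.y)
        full = evaluator.evaluate_population(theta[None])[0]
        tau[1, 3] = 0.0
        w = BootstrapWeights(tau, np.ones_like(evaluator.kd.responses))
        masked = evaluator.with_weights(w).evaluate_population(theta[None])[0]
        # explicit residual of the masked point
        from coregrn.simulate import integrate

        p = evaluator.params_from_vector(theta)
        traj = integrate(evaluator.structure, p, "sigmoid", evaluator.x0,
                         evaluator.ts.times)
        r = (evaluator.ts.y[1, 3] - traj.states[1, 3]) / evaluator.ts.sigma[1, 3]
        assert full - masked == pytest.approx(r**2, rel=1e-2)


class TestCriterionValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown criterion"):
            SelectionCriterion(kind="lasso")

    def test_cv_not_implemented(self, tiny_truth, tiny_data):
        from coregrn.objective import CostEvaluator
        from coregrn.selection import backward_eliminate

        ts, kd = tiny_data
        ev = CostEvaluator(tiny_truth.structure.core_subsystem(), ts, kd)
        with pytest.raises(NotImplementedError):
            backward_eliminate(ev, SelectionCriterion(kind="cv"))

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="stop_index"):
            _trace([("A", "B")], [("A", "B")], stop=5)
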