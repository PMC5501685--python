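import numpy as np
import pytest

import coregrn as c
from coregrn.data import BootstrapWeights
from coregrn.objective import CostEvaluator, cost
from coregrn.simulate import integrate, apply_knockdown


@pytest.fixture(scope="module")
def setup(tiny_truth, tiny_data):
    ts, kd = tiny_data
    core = tiny_truth.structure.core_subsystem()
    ev = CostEvaluator(core, ts, kd)
    return tiny_truth, ts, kd, core, ev


def _brute_force_cost(params, structure, ts, kd, weights=None):
    """Independent oracle: explicit sum over every data point."""
    x0 = ts.y[:, 0]
    traj = integrate(structure, params, "sigmoid", x0, ts.times)
    tau_ts = weights.tau_timeseries if weights else np.ones_like(ts.y)
    tau_kd = weights.tau_knockdown if weights else np.ones_like(kd.responses)
    V = 0.0
    for i in range(len(ts.genes)):
        for j in range(ts.times.size):
            V += tau_ts[i, j] * (ts.y[i, j] - traj.states[i, j]) ** 2 / ts.sigma[i, j] ** 2
    for e, spec in enumerate(kd.specs):
        times = np.array([ts.times[0], spec.measurement_time])
        wt = integrate(structure, params, "sigmoid", x0, times)
        kdp = apply_knockdown(params, spec)
        kt = integrate(structure, kdp, "sigmoid", x0, times)
        model = np.clip(np.log2(kt.states[:, -1] / wt.states[:, -1]), -2, 2)
        for i in range(len(kd.genes)):
            V += tau_kd[e, i] * (model[i] - kd.responses[e, i]) ** 2  # sigma = 1
    return V


class TestCost:
    def test_perfect_fit_costs_zero(self, tiny_truth):
        """Noiseless data generated by the model itself has V ~ 0."""
        truth = c.generate_truth(3, 0, seed=21, noise_sd=0.0)
        ts, kd = c.generate_data(truth, seed=22)
        V = cost(truth.params, truth.structure, "sigmoid", ts, kd, x0=truth.x0)
        assert V == pytest.approx(0.0, abs=1e-4)

    def test_reference_cost_matches_brute_force_sum(self, setup):
        truth, ts, kd, core, ev = setup
        params = ev.params_from_vector(
            np.concatenate([truth.params.lambda_, truth.params.xi,
                            [truth.params.w[e] for e in ev.free_edges]])
        )
        expected = _brute_force_cost(params, core, ts.subset(core.genes),
                                     kd.subset(core.genes))
        got = cost(params, core, "sigmoid", ts, kd)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_fast_evaluator_agrees_with_reference(self, setup, rng):
        truth, ts, kd, core, ev = setup
        lo = np.array([b[0] for b in ev.bounds])
        hi = np.array([b[1] for b in ev.bounds])
        for _ in range(5):
            theta = rng.uniform(lo, hi)
            theta[: ev.n_genes] = rng.uniform(0.3, 6, ev.n_genes)
            theta[ev.n_genes: 2 * ev.n_genes] = rng.uniform(0.3, 4, ev.n_genes)
            p = ev.params_from_vector(theta)
            v_fast = ev.cost_params(p)
            v_ref = cost(p, core, "sigmoid", ts, kd)
            # a few percent in extreme (stiff/saturated) corners of the box;
            # accuracy near plausible parameters is far tighter (see below)
            assert v_fast == pytest.approx(v_ref, rel=3e-2)
        p = ev.params_from_vector(
            np.concatenate([rng.uniform(0.5, 4, ev.n_genes),
                            rng.uniform(0.5, 2.5, ev.n_genes),
                            rng.uniform(-8, 8, len(ev.free_edges))])
        )
        assert ev.cost_params(p) == pytest.approx(
            cost(p, core, "sigmoid", ts, kd), rel=1e-3
        )

    def test_all_ones_weights_equal_unweighted(self, setup, rng):
        truth, ts, kd, core, ev = setup
        theta = ev.vector_from_params(truth.params) * 0 + 1.0
        ones = BootstrapWeights.ones(ts.subset(core.genes), kd.subset(core.genes))
        v1 = ev.evaluate_population(theta[None])[0]
        v2 = ev.with_weights(ones).evaluate_population(theta[None])[0]
        assert v1 == v2

    def test_zero_weights_annihilate_cost(self, setup):
        truth, ts, kd, core, ev = setup
        zeros = BootstrapWeights(
            np.zeros_like(ev.ts.y), np.zeros_like(ev.kd.responses)
        )
        theta = np.ones(ev.n_params)
        assert ev.with_weights(zeros).evaluate_population(theta[None])[0] == 0.0

    def test_weighted_cost_matches_brute_force(self, setup, rng):
        truth, ts, kd, core, ev = setup
        ts_c, kd_c = ts.subset(core.genes), kd.subset(core.genes)
        w = BootstrapWeights.sample(ts_c, kd_c, rng)
        params = ev.params_from_vector(rng.uniform(0.3, 2.0, ev.n_params))
        expected = _brute_force_cost(params, core, ts_c, kd_c, weights=w)
        got = cost(params, core, "sigmoid", ts, kd, weights=w)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_point_weight_increase_never_decreases_cost(self, setup, rng):
        truth, ts, kd, core, ev = setup
        theta = rng.uniform(0.5, 2.0, ev.n_params)
        tau = np.ones_like(ev.ts.y)
        tau[0, 2] = 0.0
        w0 = BootstrapWeights(tau, np.ones_like(ev.kd.responses))
        v_without = ev.with_weights(w0).evaluate_population(theta[None])[0]
        v_with = ev.evaluate_population(theta[None])[0]
        assert v_with >= v_without

    def test_integration_failure_returns_inf(self, setup):
        truth, ts, kd, core, ev = setup
        bad = truth.params.copy()
        bad.lambda_ = bad.lambda_ * 0 - 5.0  # negative rates: divergence guard
        assert cost(bad, core, "sigmoid", ts, kd) == np.inf or np.isfinite(
            cost(bad, core, "sigmoid", ts, kd)
        )


class TestEvaluatorMechanics:
    def test_vector_round_trip(self, setup, rng):
        *_, ev = setup
        theta = rng.uniform(0.1, 5.0, ev.n_params)
        np.testing.assert_allclose(
            ev.vector_from_params(ev.params_from_vector(theta)), theta
        )

    def test_with_free_edges_shrinks_layout(self, setup):
        *_, ev = setup
        sub = ev.with_free_edges(ev.free_edges[:1])
        assert sub.n_params == 2 * ev.n_genes + 1
        assert len(sub.bounds) == sub.n_params

    def test_scipy_convention_both_shapes(self, setup, rng):
        *_, ev = setup
        theta = rng.uniform(0.5, 2.0, ev.n_params)
        single = ev(theta)
        batch = ev(np.column_stack([theta, theta]))
        assert batch.shape == (2,)
        assert single == pytest.approx(batch[0])
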