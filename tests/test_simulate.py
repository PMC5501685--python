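import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coregrn as c
from coregrn.kinetics import KineticParameters
from coregrn.network import NetworkStructure
from coregrn.simulate import (
    IntegrationError,
    KnockdownSpec,
    apply_knockdown,
    etd2rk_integrate,
    integrate,
    make_grid,
    simulate_knockdown_response,
)


def _decay_params(lam=1.0, xi=2.0):
    return KineticParameters(("A",), np.array([lam]), np.array([xi]), {})


class TestIntegrate:
    def test_starting_at_steady_state_stays_constant(self, decay_structure):
        # lam=1, xi=2 => xi*sigma(0)/lam = 1
        traj = integrate(
            decay_structure, _decay_params(), "sigmoid", np.array([1.0]),
            np.linspace(0, 10, 11),
        )
        np.testing.assert_allclose(traj.states, 1.0, atol=1e-6)

    def test_matches_closed_form_relaxation(self, decay_structure):
        # dx/dt = -x + 1 from x0=0: x(t) = 1 - exp(-t)
        times = np.array([0.0, 0.5, 1.0, 2.0])
        traj = integrate(
            decay_structure, _decay_params(), "sigmoid", np.array([0.0]), times
        )
        expected = 1.0 - np.exp(-times)
        np.testing.assert_allclose(traj.states[0], expected, rtol=1e-4, atol=1e-6)

    def test_deterministic_bit_identical(self, tiny_truth):
        t = tiny_truth
        times = np.linspace(0, 12, 7)
        a = integrate(t.structure, t.params, "sigmoid", t.x0, times)
        b = integrate(t.structure, t.params, "sigmoid", t.x0, times)
        assert np.array_equal(a.states, b.states)

    def test_agrees_with_fixed_step_rk4_reference(self, tiny_truth):
        """Independent oracle: hand-rolled RK4 at small step on 3 genes."""
        t = tiny_truth
        times = np.linspace(0, 6, 4)
        traj = integrate(t.structure, t.params, "sigmoid", t.x0, times)

        from coregrn.kinetics import rhs

        h = 1e-3
        x = t.x0.copy()
        rk4 = [x.copy()]
        grid_targets = times[1:]
        tt = 0.0
        for target in grid_targets:
            n = int(round((target - tt) / h))
            for _ in range(n):
                k1 = rhs(x, t.params, t.structure)
                k2 = rhs(x + h / 2 * k1, t.params, t.structure)
                k3 = rhs(x + h / 2 * k2, t.params, t.structure)
                k4 = rhs(x + h * k3, t.params, t.structure)
                x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            tt = target
            rk4.append(x.copy())
        np.testing.assert_allclose(traj.states, np.array(rk4).T, rtol=1e-4)

    def test_bad_inputs_rejected(self, decay_structure):
        with pytest.raises(ValueError, match="strictly increasing"):
            integrate(decay_structure, _decay_params(), "sigmoid",
                      np.array([0.0]), [0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="finite"):
            integrate(decay_structure, _decay_params(), "sigmoid",
                      np.array([np.inf]), [0.0, 1.0])


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_sigmoid_system_bounded_for_positive_rates(seed):
    """Trajectories stay below max(xi/lambda) + x0 over long horizons."""
    rng = np.random.default_rng(seed)
    s = NetworkStructure(
        ("A", "B", "C"), (),
        (("A", "B"), ("B", "C"), ("C", "A")),
        frozenset({("A", "B"), ("B", "C"), ("C", "A")}),
    )
    lam = rng.uniform(0.05, 20.0, 3)
    xi = rng.uniform(0.05, 20.0, 3)
    w = {e: float(rng.uniform(-20, 20)) for e in s.allowed_edges}
    p = KineticParameters(s.genes, lam, xi, w)
    x0 = rng.uniform(0, 2, 3)
    traj = integrate(s, p, "sigmoid", x0, np.linspace(0, 100, 51))
    bound = np.max(xi / lam) + np.max(x0) + 1e-6
    assert np.all(traj.states <= bound)
    assert np.all(traj.states >= -1e-9)


class TestFastIntegrator:
    def test_matches_reference_solver(self, tiny_truth):
        t = tiny_truth
        times = np.linspace(0, 12, 7)
        ref = integrate(t.structure, t.params, "sigmoid", t.x0, times)

        W = t.params.w_matrix(t.structure)
        xi = t.params.xi
        from scipy.special import expit

        grid, idx = make_grid(0.0, times, 0.02)
        rec = [idx[float(x)] for x in times]
        out = etd2rk_integrate(
            lambda x: xi * expit(W @ x), t.params.lambda_, t.x0, grid, rec
        )
        np.testing.assert_allclose(out.T, ref.states, rtol=2e-3, atol=1e-5)

    def test_exact_for_pure_decay(self):
        # lam x' = -2x: exponential integrator is exact at any step
        grid = np.array([0.0, 1.0, 2.0, 5.0])
        out = etd2rk_integrate(
            lambda x: np.zeros_like(x), np.array([2.0]), np.array([3.0]), grid
        )
        np.testing.assert_allclose(out[:, 0], 3.0 * np.exp(-2.0 * grid), rtol=1e-12)

    def test_zero_lambda_series_limit(self):
        # lam = 0 with constant production a: x(t) = x0 + a t (Heun limit)
        grid = np.linspace(0, 4, 9)
        out = etd2rk_integrate(
            lambda x: np.full_like(x, 1.5), np.array([0.0]), np.array([0.0]), grid
        )
        np.testing.assert_allclose(out[:, 0], 1.5 * grid, rtol=1e-10, atol=1e-12)

    def test_make_grid_hits_every_event(self):
        grid, idx = make_grid(0.0, [0.0, 1.0, 2.5], 0.4)
        for t, i in idx.items():
            assert grid[i] == pytest.approx(t)
        assert np.all(np.diff(grid) > 0)
        assert np.max(np.diff(grid)) <= 0.4 + 1e-12


class TestKnockdown:
    def test_lambda_scaling_arithmetic(self):
        p = _decay_params(lam=2.0)
        kd = apply_knockdown(p, KnockdownSpec("A", 0.5, 10.0))
        assert kd.lambda_[0] == pytest.approx(4.0)
        kd = apply_knockdown(_decay_params(lam=1.0), KnockdownSpec("A", 0.25, 10.0))
        assert kd.lambda_[0] == pytest.approx(4.0)

    def test_unit_fold_change_is_identity(self):
        p = _decay_params(lam=3.0)
        kd = apply_knockdown(p, KnockdownSpec("A", 1.0, 10.0))
        assert kd.lambda_[0] == pytest.approx(3.0)
        assert p.lambda_[0] == 3.0  # original untouched

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="fold_change"):
            KnockdownSpec("A", 0.0, 10.0)
        with pytest.raises(KeyError, match="unknown"):
            apply_knockdown(_decay_params(), KnockdownSpec("Z", 0.5, 10.0))

    def test_unit_fold_change_gives_zero_response(self, tiny_truth):
        t = tiny_truth
        spec = KnockdownSpec(t.structure.core_genes[0], 1.0, 12.0)
        resp = simulate_knockdown_response(
            t.structure, t.params, "sigmoid", spec, t.x0
        )
        np.testing.assert_allclose(resp, 0.0, atol=1e-9)

    def test_target_without_outgoing_edges_leaves_others_at_zero(self):
        s = NetworkStructure(("A", "B"), ())
        p = KineticParameters(("A", "B"), np.array([1.0, 1.0]), np.array([2.0, 2.0]), {})
        resp = simulate_knockdown_response(
            s, p, "sigmoid", KnockdownSpec("A", 0.4, 20.0), np.array([1.0, 1.0])
        )
        assert resp[0] < 0  # stronger degradation lowers the target itself
        assert resp[1] == pytest.approx(0.0, abs=1e-7)

    def test_responses_clipped_to_minus2_plus2(self):
        s = NetworkStructure(("A",), ())
        p = KineticParameters(("A",), np.array([1.0]), np.array([2.0]), {})
        # fold change 0.05 -> lambda 20x: log2 ratio far below -2 -> clipped
        resp = simulate_knockdown_response(
            s, p, "sigmoid", KnockdownSpec("A", 0.05, 50.0), np.array([1.0])
        )
        assert resp[0] == pytest.approx(-2.0)

    def test_non_core_target_rejected(self):
        s = c.build_structure([("A", "P")], ["A"], ["A", "P"])
        p = KineticParameters(("A", "P"), np.ones(2), np.ones(2), {("A", "P"): 1.0})
        with pytest.raises(ValueError, match="not a core gene"):
            simulate_knockdown_response(
                s, p, "sigmoid", KnockdownSpec("P", 0.5, 10.0), np.ones(2)
            )
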