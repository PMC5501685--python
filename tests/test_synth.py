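import numpy as np
import pytest

import coregrn as c
from coregrn.kinetics import KineticParameters
from coregrn.network import NetworkStructure
from coregrn.objective import CostEvaluator
from coregrn.selection import chi2_assess
from coregrn.synth import (
    MIN_EDGE_INPUT,
    U_STAR_RANGE,
    corrupt_prior,
    generate_data,
    generate_truth,
    n_decoys_for_fraction,
    recovery_metrics,
    sign_agreement,
)


class TestGenerateTruth:
    def test_deterministic_in_seed(self):
        a = c.generate_truth(4, 2, seed=5)
        b = c.generate_truth(4, 2, seed=5)
        assert a.structure.allowed_edges == b.structure.allowed_edges
        np.testing.assert_array_equal(a.params.lambda_, b.params.lambda_)
        np.testing.assert_array_equal(a.x0, b.x0)
        assert a.params.w == b.params.w

    def test_core_only_when_no_peripheral(self):
        t = c.generate_truth(4, 0, seed=1)
        assert t.structure.peripheral_genes == ()

    def test_parameters_in_declared_ranges(self):
        t = c.generate_truth(5, 3, seed=2)
        assert np.all(t.params.lambda_ >= 0.5) and np.all(t.params.lambda_ <= 5.0)
        t.params.validate(t.structure)  # inside the search box
        mags = np.abs(list(t.params.w.values()))
        assert np.all(mags <= 10.0 + 1e-9)

    def test_core_contains_a_feedback_cycle(self):
        import networkx as nx

        t = c.generate_truth(5, 0, core_density=0.4, seed=3)
        g = nx.DiGraph(list(t.structure.core_subsystem().active_edges))
        assert not nx.is_directed_acyclic_graph(g)

    def test_regulatory_inputs_in_responsive_range(self):
        """Steady-state summed inputs avoid sigmoid saturation and every
        edge carries a visible input share (identifiable-by-design)."""
        t = c.generate_truth(5, 4, seed=4)
        gi = t.structure.gene_index
        traj = c.integrate(t.structure, t.params, "sigmoid", t.x0,
                           np.array([0.0, 60.0]))
        x_star = traj.states[:, -1]
        for g in t.structure.genes:
            in_edges = t.structure.allowed_in_edges(g)
            if not in_edges:
                continue
            u = sum(t.params.w[e] * x_star[gi[e[0]]] for e in in_edges)
            assert U_STAR_RANGE[0] - 0.5 <= u <= U_STAR_RANGE[1] + 0.5

    def test_infeasible_requests_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            c.generate_truth(1, 0)
        with pytest.raises(ValueError, match="in_degree"):
            c.generate_truth(3, 2, peripheral_in_degree=5)


class TestGenerateData:
    def test_noiseless_limit_equals_exact_trajectory(self):
        t = c.generate_truth(3, 0, seed=7, noise_sd=0.0)
        ts, kd = generate_data(t, seed=8)
        traj = c.integrate(t.structure, t.params, "sigmoid", t.x0, ts.times)
        for j, block in enumerate(ts.replicates):
            expected = np.repeat(traj.states[:, [j]], block.shape[1], axis=1)
            np.testing.assert_allclose(block, expected, rtol=1e-9)

    def test_replicate_design_shape(self, tiny_truth):
        ts, kd = generate_data(tiny_truth, times=(0, 1, 2, 4, 8, 12),
                               n_replicates=3, seed=1)
        assert ts.times.size == 6
        assert all(b.shape[1] == 3 for b in ts.replicates)  # 18 samples/gene
        assert kd.responses.shape == (len(tiny_truth.structure.core_genes),
                                      tiny_truth.structure.n_genes)

    def test_deterministic_in_seed(self, tiny_truth):
        a = generate_data(tiny_truth, seed=3)
        b = generate_data(tiny_truth, seed=3)
        np.testing.assert_array_equal(a[0].y, b[0].y)
        np.testing.assert_array_equal(a[1].responses, b[1].responses)

    def test_no_knockdowns_when_requested(self, tiny_truth):
        ts, kd = generate_data(tiny_truth, knockdown_targets=(), seed=1)
        assert kd is None

    def test_knockdown_of_isolated_tf_only_moves_itself(self):
        s = NetworkStructure(("TF1", "TF2"), ())
        p = KineticParameters(("TF1", "TF2"), np.array([1.0, 1.0]),
                              np.array([1.0, 1.0]), {})
        truth = c.SyntheticTruth(s, p, np.array([0.3, 0.3]), 0.0, 0)
        ts, kd = generate_data(truth, times=(0, 2, 4), seed=2)
        for row, spec in zip(kd.responses, kd.specs):
            i = s.genes.index(spec.target_gene)
            other = 1 - i
            assert row[i] < 0
            assert row[other] == pytest.approx(0.0, abs=1e-6)

    def test_truth_passes_its_own_chi2_calibration(self, tiny_truth):
        """The generated system is consistent with its own noise model:
        the truth's cost stays under the chi-square limit in >= 95% of
        simulated datasets."""
        t = tiny_truth
        ok = 0
        n_rep = 40
        for r in range(n_rep):
            ts, kd = generate_data(t, seed=1000 + r)
            ev = CostEvaluator(t.structure, ts, kd, x0=t.x0)
            v = ev.cost_params(t.params)
            crit, rejected = chi2_assess(v, ev.n_data_points)
            ok += not rejected
        assert ok / n_rep >= 0.95


class TestCorruptPrior:
    def test_zero_decoys_returns_truth(self, tiny_truth):
        prior = corrupt_prior(tiny_truth.structure, 0, seed=1)
        assert set(prior) == set(tiny_truth.true_edges)

    def test_decoys_have_core_regulators_and_no_duplicates(self, tiny_truth):
        prior = corrupt_prior(tiny_truth.structure, 3, seed=2)
        assert len(prior) == len(set(prior))
        core = set(tiny_truth.structure.core_genes)
        assert all(r in core for r, _ in prior)
        assert set(tiny_truth.true_edges) <= set(prior)

    def test_same_seed_same_prior(self, tiny_truth):
        assert corrupt_prior(tiny_truth.structure, 3, seed=5) == corrupt_prior(
            tiny_truth.structure, 3, seed=5
        )

    def test_too_many_decoys_rejected(self, tiny_truth):
        with pytest.raises(ValueError, match="decoys"):
            corrupt_prior(tiny_truth.structure, 10_000, seed=1)

    def test_decoy_fraction_arithmetic(self):
        assert n_decoys_for_fraction(8, 0.45) == 7
        assert n_decoys_for_fraction(10, 0.0) == 0


class TestRecoveryMetrics:
    def test_perfect_recovery(self, tiny_truth):
        s = tiny_truth.structure
        ranks = {e: i + 1 for i, e in enumerate(s.allowed_edges)}
        m = recovery_metrics(s, s, removal_ranks=None)
        assert m["precision"] == 1.0 and m["recall"] == 1.0

    def test_complement_has_zero_precision(self, tiny_truth):
        s = tiny_truth.structure
        empty = s.with_active(frozenset())
        m = recovery_metrics(empty, s)
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_perfect_ranking_auc_is_one(self, tiny_truth):
        s = tiny_truth.structure
        decoys = [("TF01", "TF03"), ("TF02", "TF01")]
        decoys = [d for d in decoys if d not in s.active_edges]
        ranks = {e: 10 for e in s.active_edges} | {d: 1 for d in decoys}
        m = recovery_metrics(s, s, removal_ranks=ranks)
        assert m["auc"] == 1.0

    def test_random_ranking_auc_near_half(self, tiny_truth, rng):
        s = tiny_truth.structure
        prior = corrupt_prior(s, 3, seed=9)
        aucs = []
        for _ in range(200):
            ranks = {e: r for e, r in zip(prior, rng.permutation(len(prior)))}
            aucs.append(recovery_metrics(s, s, removal_ranks=ranks)["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_disjoint_universes_rejected(self, tiny_truth):
        other = NetworkStructure(("X", "Y"))
        with pytest.raises(ValueError, match="different genes"):
            recovery_metrics(other, tiny_truth.structure)

    def test_sign_agreement(self, tiny_truth):
        t = tiny_truth
        flipped = t.params.copy()
        assert sign_agreement(t.params, t) == 1.0
        e0 = next(iter(flipped.w))
        flipped.w[e0] = -flipped.w[e0]
        expected = 1.0 - 1.0 / len(flipped.w)
        assert sign_agreement(flipped, t) == pytest.approx(expected)
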