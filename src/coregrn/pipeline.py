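"""Two-step inference pipeline, model assembly and validation statistics.

Step 1 (:class:`CoreNetworkInference`) fits the core transcription-factor
subsystem jointly to time-series and knockdown data and prunes it by
backward elimination.  Step 2 (:class:`PeripheralInference`) then treats
the simulated core trajectories as a fixed drive and solves every
peripheral gene independently — peripheral genes have no feedback to the
core and no crosstalk, so their fits decouple exactly and parallelize
trivially.  The two pieces assemble into one simulatable genome-scale
model.

Validation machinery: null ensembles resampled from the prior with matched
edge count and sign distribution, empirical-p comparison of model cost
against null costs, a permutation test for external edge scores
(removed-vs-remaining), and hidden-point prediction against a linear-
interpolation baseline.

Both inference classes follow the scikit-learn estimator protocol
(``get_params``/``set_params``, ``fit``, fitted attributes with a trailing
underscore); :func:`infer_core` and :func:`infer_peripheral` are thin
functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from sklearn.base import BaseEstimator

from . import kinetics as kin
from .data import BootstrapWeights, ExpressionTimeSeries, KnockdownDataset
from .kinetics import KineticParameters, get_kinetics
from .network import Edge, NetworkStructure
from .objective import _TINY, CostEvaluator
from .optimize import DEFAULT_POPSIZE, FitResult, fit
from .selection import PruningTrace, SelectionCriterion, backward_eliminate, chi2_assess
from .simulate import apply_knockdown, integrate, make_grid

logger = logging.getLogger(__name__)

__all__ = [
    "CoreNetworkInference",
    "PeripheralInference",
    "PeripheralFit",
    "FullModel",
    "NullEnsemble",
    "infer_core",
    "infer_peripheral",
    "assemble",
    "sample_null_structures",
    "refit_fixed_signs",
    "refit_null_ensemble",
    "compare_to_null",
    "edge_validation_permutation",
    "predict_hidden_point",
]


# ---------------------------------------------------------------------------
# Step 1: core inference
# ---------------------------------------------------------------------------


class CoreNetworkInference(BaseEstimator):
    """Fit and prune the core subsystem (Step 1).

    Parameters mirror the method's tunables: kinetics form, stop criterion
    (kind, heuristic multiplier c, significance level alpha), population
    size and evaluation budgets of the global search, the fast-integrator
    step ``dt``, and the master ``random_state``.

    Fitted attributes
    -----------------
    structure_ : NetworkStructure
        Core subsystem with pruned edges deactivated.
    params_ : KineticParameters
        Parameters of the minimal model (at the stop point).
    trace_ : PruningTrace
    cost_ : float
        V at the stop point.
    chi2_critical_, rejected_ : chi-square assessment at df = #data points.
    identifiability_warning_ : bool
        Set when no knockdown data were supplied (structural
        identifiability is then substantially reduced).
    """

    def __init__(
        self,
        kinetics="sigmoid",
        criterion: str = "heuristic_std",
        c: float = 0.05,
        alpha: float = 0.05,
        population_size: int = 80,
        budget: int = 20000,
        initial_starts: int = 2,
        refit_budget: int = 2000,
        dt: float = 0.1,
        random_state: int = 0,
    ):
        self.kinetics = kinetics
        self.criterion = criterion
        self.c = c
        self.alpha = alpha
        self.population_size = population_size
        self.budget = budget
        self.initial_starts = initial_starts
        self.refit_budget = refit_budget
        self.dt = dt
        self.random_state = random_state

    def _criterion(self) -> SelectionCriterion:
        return SelectionCriterion(kind=self.criterion, c=self.c, alpha=self.alpha)

    def fit(
        self,
        timeseries: ExpressionTimeSeries,
        knockdowns: KnockdownDataset | None = None,
        structure: NetworkStructure | None = None,
    ):
        if structure is None:
            raise ValueError("a prior NetworkStructure is required")
        core = structure.core_subsystem()
        if not core.core_genes:
            raise ValueError("structure has an empty core")
        self.identifiability_warning_ = knockdowns is None
        if self.identifiability_warning_:
            logger.warning(
                "no knockdown data supplied: structural identifiability of the "
                "core system is reduced"
            )
        kd = None
        if knockdowns is not None:
            keep = [
                e for e, s in enumerate(knockdowns.specs)
                if s.target_gene in core.core_genes
            ]
            kd = KnockdownDataset(
                knockdowns.genes,
                tuple(knockdowns.specs[e] for e in keep),
                knockdowns.responses[keep],
                knockdowns.clip,
            )

        ev = CostEvaluator(
            core, timeseries, kd, kinetics=self.kinetics, dt=self.dt
        )
        self.evaluator_ = ev
        if not core.allowed_edges:
            # degenerate prior: pure decay/basal model, nothing to prune
            res = fit(
                ev, ev.bounds, self.random_state,
                budget=self.budget, popsize=self.population_size, vectorized=True,
            )
            self.fit_result_ = res
            self.params_ = ev.params_from_vector(res.x)
            self.trace_ = PruningTrace(
                (), (), np.empty(0), res.best_cost, 0, core, self.params_,
                seed=self.random_state,
            )
            self.cost_ = res.best_cost
        else:
            trace, res = backward_eliminate(
                ev,
                criterion=self._criterion(),
                seed=self.random_state,
                initial_budget=self.budget,
                initial_starts=self.initial_starts,
                refit_budget=self.refit_budget,
                popsize=self.population_size,
            )
            self.fit_result_ = res
            self.trace_ = trace
            self.params_ = trace.params_at_stop
            path = np.concatenate(([trace.initial_cost], trace.cost_at_step))
            self.cost_ = float(path[trace.stop_index])
        self.structure_ = self.trace_.final_structure
        self.chi2_critical_, self.rejected_ = chi2_assess(
            self.cost_, ev.n_data_points, self.alpha
        )
        return self


def infer_core(structure, timeseries, knockdowns=None, config=None, seed=0):
    """Functional wrapper around :class:`CoreNetworkInference`.

    Returns ``(fit_result, trace)``; ``config`` is a dict of estimator
    parameters.
    """
    est = CoreNetworkInference(random_state=seed, **(config or {}))
    est.fit(timeseries, knockdowns, structure=structure)
    return est.fit_result_, est.trace_


# ---------------------------------------------------------------------------
# Step 2: peripheral inference driven by fixed core trajectories
# ---------------------------------------------------------------------------


class CoreDrive:
    """Precomputed core trajectories (wild type and per knockdown).

    The core solution is computed once with the adaptive reference solver
    and sampled on the fast-integration grid; every peripheral gene fit
    then reads the same drive.  System k = 0 is wild type, k = e + 1 the
    system for knockdown experiment e.
    """

    def __init__(
        self,
        core_structure: NetworkStructure,
        core_params: KineticParameters,
        kinetics,
        times,
        kd_specs=(),
        x0_core: np.ndarray | None = None,
        dt: float = 0.1,
    ):
        self.core_structure = core_structure
        self.core_params = core_params
        self.kinetics = get_kinetics(kinetics)
        self.times = np.asarray(times, float)
        self.kd_specs = tuple(kd_specs)
        self.dt = float(dt)
        t0 = float(self.times[0])
        events = {float(t) for t in self.times} | {
            float(s.measurement_time) for s in self.kd_specs
        }
        self.grid, event_idx = make_grid(t0, events, dt)
        self.ts_idx = np.array([event_idx[float(t)] for t in self.times])
        self.kd_idx = np.array(
            [event_idx[float(s.measurement_time)] for s in self.kd_specs], dtype=int
        )
        if x0_core is None:
            raise ValueError("x0_core is required")
        systems = [core_params] + [apply_knockdown(core_params, s) for s in self.kd_specs]
        states = []
        for p in systems:
            traj = integrate(core_structure, p, self.kinetics, x0_core, self.grid)
            states.append(traj.states.T)  # (n_grid, n_core)
        self.states = np.stack(states)  # (K, n_grid, n_core)

    @property
    def n_systems(self) -> int:
        return 1 + len(self.kd_specs)


class DrivenGeneCostEvaluator:
    """Objective for one peripheral gene under a fixed core drive.

    Same duck-typed surface as :class:`~coregrn.objective.CostEvaluator`
    (bounds, packing, ``with_free_edges``, population evaluation) so the
    same backward-elimination code prunes per-gene in-edges.  The gene's
    ODE is scalar with a known time-varying production input, which the
    exponential-trapezoidal recurrence integrates cheaply and stably for a
    whole population at once.
    """

    def __init__(
        self,
        gene: str,
        structure: NetworkStructure,
        drive: CoreDrive,
        timeseries: ExpressionTimeSeries,
        knockdowns: KnockdownDataset | None = None,
        free_edges=None,
        weights=None,
        x0: float | None = None,
    ):
        self.gene = gene
        self.structure = structure
        self.drive = drive
        self.kinetics = drive.kinetics
        gi = timeseries.genes.index(gene)
        self.y = timeseries.y[gi]
        self.sigma = timeseries.sigma[gi]
        self.times = timeseries.times
        self.ts = timeseries
        if free_edges is None:
            free_edges = [e for e in structure.allowed_in_edges(gene) if e in structure.active_edges]
        self.free_edges = tuple(free_edges)
        self.kd = knockdowns
        if knockdowns is not None:
            if tuple(knockdowns.specs) != drive.kd_specs:
                raise ValueError("knockdown specs do not match the core drive")
            self.kd_responses = knockdowns.responses[:, knockdowns.genes.index(gene)]
        else:
            self.kd_responses = np.empty(0)
        if weights is None:
            tau_kd = np.ones_like(self.kd_responses) if self.kd is not None else None
            weights = BootstrapWeights(np.ones_like(self.y), tau_kd)
        self.weights = weights
        self.x0 = float(self.y[0]) if x0 is None else float(x0)
        core_index = {g: i for i, g in enumerate(drive.core_structure.genes)}
        self._reg_idx = np.array([core_index[r] for r, _ in self.free_edges], dtype=int)

    # -- packing (layout: [lambda, xi, w...]) ------------------------------

    @property
    def n_genes(self) -> int:
        return 1

    @property
    def n_params(self) -> int:
        return 2 + len(self.free_edges)

    @property
    def n_data_points(self) -> int:
        return self.y.size + self.kd_responses.size

    @property
    def bounds(self):
        return [kin.LAMBDA_BOUNDS, kin.XI_BOUNDS] + [kin.W_BOUNDS] * len(self.free_edges)

    def params_from_vector(self, theta) -> KineticParameters:
        theta = np.asarray(theta, float)
        w = dict(zip(self.free_edges, theta[2:]))
        return KineticParameters((self.gene,), theta[:1].copy(), theta[1:2].copy(), w)

    def vector_from_params(self, params: KineticParameters) -> np.ndarray:
        theta = np.empty(self.n_params)
        theta[0] = params.lambda_[0]
        theta[1] = params.xi[0]
        theta[2:] = [params.w.get(e, 0.0) for e in self.free_edges]
        return theta

    def with_free_edges(self, free_edges) -> "DrivenGeneCostEvaluator":
        ev = DrivenGeneCostEvaluator.__new__(DrivenGeneCostEvaluator)
        ev.__dict__.update(self.__dict__)
        ev.free_edges = tuple(free_edges)
        core_index = {g: i for i, g in enumerate(self.drive.core_structure.genes)}
        ev._reg_idx = np.array([core_index[r] for r, _ in ev.free_edges], dtype=int)
        return ev

    def with_weights(self, weights) -> "DrivenGeneCostEvaluator":
        ev = DrivenGeneCostEvaluator.__new__(DrivenGeneCostEvaluator)
        ev.__dict__.update(self.__dict__)
        ev.weights = weights
        return ev

    def warm_start(self) -> np.ndarray:
        """Knockdown-sign-oriented initial vector (see CostEvaluator)."""
        from scipy.special import expit

        x_star = max(float(self.y[-1]), 1e-3)
        lam = 1.5
        w = np.empty(len(self.free_edges))
        for j, (r, _) in enumerate(self.free_edges):
            resp = 0.0
            for k, spec in enumerate(self.drive.kd_specs):
                if spec.target_gene == r:
                    resp = float(self.kd_responses[k]) if self.kd_responses.size else 0.0
            w[j] = -np.sign(resp) * min(8.0, max(1.0, 4.0 * abs(resp))) if resp else 1.0
        core_star = self.drive.states[0, -1, :]
        u = float(w @ core_star[self._reg_idx]) if len(w) else 0.0
        xi = float(np.clip(lam * x_star / expit(np.clip(u, -4.0, 4.0)), 1e-2, 20.0))
        return np.concatenate(([lam, xi], w))

    # -- evaluation --------------------------------------------------------

    def evaluate_population(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        S = X.shape[0]
        lam = np.clip(X[:, 0], 0.0, None)  # (S,)
        xi = X[:, 1]
        w = X[:, 2:]  # (S, E)
        drive = self.drive
        K, n_grid = drive.n_systems, drive.grid.size

        # regulatory input u[k, n, s] then production a at every grid node
        if len(self.free_edges):
            regs = drive.states[:, :, self._reg_idx]  # (K, n_grid, E)
            u = regs @ w.T  # (K, n_grid, S)
        else:
            u = np.zeros((K, n_grid, S))
        a = self.kinetics.production(u, xi[None, None, :])

        h = np.diff(drive.grid)
        x = np.broadcast_to(self.x0, (K, S)).copy()
        out = np.empty((K, n_grid, S))
        out[:, 0, :] = x
        coeff = {}
        for n in range(n_grid - 1):
            key = round(float(h[n]), 12)
            if key not in coeff:
                z = lam * h[n]
                e = np.exp(-z)
                small = np.abs(z) < 1e-5
                zs = np.where(small, 1.0, z)
                c1 = np.where(small, h[n] * (1 - z / 2 + z * z / 6), h[n] * (1 - e) / zs)
                c2 = np.where(
                    small, h[n] * (0.5 - z / 6 + z * z / 24), h[n] * (e - 1 + z) / (zs * zs)
                )
                coeff[key] = (e, c1, c2)
            e, c1, c2 = coeff[key]
            a0 = a[:, n, :]
            a1 = a[:, n + 1, :]
            x = x * e + a0 * c1 + (a1 - a0) * c2
            out[:, n + 1, :] = x

        yhat = out[0][drive.ts_idx]  # (T, S)
        resid = (self.y[:, None] - yhat) / self.sigma[:, None]
        V = np.sum(self.weights.tau_timeseries[:, None] * resid**2, axis=0)

        if self.kd is not None and len(drive.kd_specs):
            x_wt = np.clip(out[0][drive.kd_idx], _TINY, None)  # (E, S)
            x_kd = np.clip(
                out[np.arange(1, K), drive.kd_idx], _TINY, None
            )
            lo, hi = self.kd.clip
            model = np.clip(np.log2(x_kd / x_wt), lo, hi)
            r = model - self.kd_responses[:, None]
            V += np.sum(self.weights.tau_knockdown[:, None] * r**2, axis=0)
        return np.where(np.isfinite(V), V, np.inf)

    def __call__(self, theta):
        theta = np.asarray(theta, float)
        if theta.ndim == 1:
            return float(self.evaluate_population(theta[None, :])[0])
        return self.evaluate_population(theta.T)


@dataclass
class PeripheralFit:
    """Step-2 result for one peripheral gene."""

    gene: str
    params: KineticParameters
    trace: PruningTrace | None
    cost: float
    chi2_critical: float
    rejected: bool
    flags: tuple[str, ...] = ()


class PeripheralInference(BaseEstimator):
    """Fit and prune core-to-peripheral regulation per gene (Step 2).

    Every peripheral gene is solved independently against the fixed,
    simulated core trajectories; per-gene seeds derive deterministically
    from ``random_state`` and results are identical for any ``n_workers``.
    Genes rejected by the chi-square test are flagged but kept.  Genes with
    no prior in-edges are fitted as decay-plus-basal and flagged.

    Fitted attributes: ``results_`` (gene -> PeripheralFit), ``drive_``,
    ``structure_`` (full structure with pruned peripheral edges removed).
    """

    def __init__(
        self,
        kinetics="sigmoid",
        criterion: str = "heuristic_std",
        c: float = 0.05,
        alpha: float = 0.05,
        population_size: int = 24,
        budget: int = 1500,
        refit_budget: int = 400,
        dt: float = 0.1,
        n_workers: int = 1,
        random_state: int = 0,
    ):
        self.kinetics = kinetics
        self.criterion = criterion
        self.c = c
        self.alpha = alpha
        self.population_size = population_size
        self.budget = budget
        self.refit_budget = refit_budget
        self.dt = dt
        self.n_workers = n_workers
        self.random_state = random_state

    def fit(
        self,
        core_structure: NetworkStructure,
        core_params: KineticParameters,
        timeseries: ExpressionTimeSeries,
        knockdowns: KnockdownDataset | None = None,
        structure: NetworkStructure | None = None,
        genes=None,
    ):
        """``core_structure``/``core_params`` are the fitted Step-1 output;
        ``structure`` is the full prior structure whose peripheral genes are
        to be solved (defaults to all of its peripheral genes)."""
        if structure is None:
            raise ValueError("the full prior NetworkStructure is required")
        genes = tuple(genes) if genes is not None else structure.peripheral_genes
        core_ts = timeseries.subset(core_structure.genes)
        kd_specs = knockdowns.specs if knockdowns is not None else ()
        drive = CoreDrive(
            core_structure,
            core_params,
            self.kinetics,
            timeseries.times,
            kd_specs,
            x0_core=core_ts.y[:, 0],
            dt=self.dt,
        )
        self.drive_ = drive
        criterion = SelectionCriterion(kind=self.criterion, c=self.c, alpha=self.alpha)

        def solve(k: int, gene: str) -> PeripheralFit:
            seed = int(
                np.random.SeedSequence(self.random_state, spawn_key=(1000 + k,))
                .generate_state(1)[0] % (2**31)
            )
            ev = DrivenGeneCostEvaluator(
                gene, structure, drive, timeseries, knockdowns
            )
            flags: list[str] = []
            if not ev.free_edges:
                flags.append("no_prior_in_edges")
                res = fit(
                    ev, ev.bounds, seed,
                    budget=self.budget, popsize=self.population_size, vectorized=True,
                )
                params, trace, cost = ev.params_from_vector(res.x), None, res.best_cost
            else:
                trace, _ = backward_eliminate(
                    ev,
                    criterion=criterion,
                    seed=seed,
                    initial_budget=self.budget,
                    refit_budget=self.refit_budget,
                    popsize=self.population_size,
                )
                params = trace.params_at_stop
                path = np.concatenate(([trace.initial_cost], trace.cost_at_step))
                cost = float(path[trace.stop_index])
            crit, rejected = chi2_assess(cost, ev.n_data_points, self.alpha)
            if rejected:
                flags.append("chi2_rejected")
            return PeripheralFit(gene, params, trace, cost, crit, rejected, tuple(flags))

        if self.n_workers == 1:
            fits = [solve(k, g) for k, g in enumerate(genes)]
        else:
            fits = Parallel(n_jobs=self.n_workers, backend="threading")(
                delayed(solve)(k, g) for k, g in enumerate(genes)
            )
        self.results_ = {f.gene: f for f in fits}

        active = set(structure.active_edges)
        for f in self.results_.values():
            active -= {e for e in structure.allowed_in_edges(f.gene)}
            active |= set(f.params.w)
        self.structure_ = structure.with_active(active)
        return self


def infer_peripheral(
    core_structure,
    core_params,
    timeseries,
    knockdowns=None,
    structure=None,
    genes=None,
    config=None,
    seed=0,
):
    """Functional wrapper around :class:`PeripheralInference`."""
    est = PeripheralInference(random_state=seed, **(config or {}))
    est.fit(core_structure, core_params, timeseries, knockdowns, structure, genes)
    return est.results_


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class FullModel:
    """Assembled genome-scale model: core + all peripheral fits.

    Peripheral genes draw input only from core genes, so simulating the
    assembled system reproduces each standalone Step-2 trajectory.
    """

    structure: NetworkStructure
    params: KineticParameters
    core_trace: PruningTrace | None
    peripheral: dict
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def assemble(
    core: CoreNetworkInference,
    peripheral: PeripheralInference,
    structure: NetworkStructure,
    provenance: dict | None = None,
) -> FullModel:
    """Combine fitted Step-1 and Step-2 estimators into one model."""
    genes = structure.genes
    lam = np.empty(len(genes))
    xi = np.empty(len(genes))
    w: dict[Edge, float] = dict(core.params_.w)
    core_idx = {g: i for i, g in enumerate(core.params_.genes)}
    for i, g in enumerate(genes):
        if g in core_idx:
            lam[i] = core.params_.lambda_[core_idx[g]]
            xi[i] = core.params_.xi[core_idx[g]]
        else:
            f = peripheral.results_[g]
            lam[i] = f.params.lambda_[0]
            xi[i] = f.params.xi[0]
            w.update(f.params.w)
    active = set(core.structure_.active_edges) | {
        e for f in peripheral.results_.values() for e in f.params.w
    }
    full_structure = structure.with_active(active)
    params = KineticParameters(genes, lam, xi, w)
    diagnostics = {
        "core_cost": core.cost_,
        "core_rejected": core.rejected_,
        "per_gene_cost": {g: f.cost for g, f in peripheral.results_.items()},
        "per_gene_rejected": {g: f.rejected for g, f in peripheral.results_.items()},
    }
    return FullModel(full_structure, params, core.trace_, dict(peripheral.results_),
                     diagnostics, provenance or {})


def simulate_driven_gene(
    gene_params: KineticParameters,
    regulators: tuple[str, ...],
    core_solution,
    core_genes: tuple[str, ...],
    x0: float,
    times,
    kinetics="sigmoid",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> np.ndarray:
    """Standalone Step-2 trajectory: one gene driven by a core solution.

    ``core_solution`` is a callable t -> core state vector (e.g. a dense
    solver output or spline).  Used by the decoupling check and hidden-point
    prediction.
    """
    from scipy.integrate import solve_ivp

    kinetics = get_kinetics(kinetics)
    lam, xi = float(gene_params.lambda_[0]), float(gene_params.xi[0])
    gene = gene_params.genes[0]
    reg_idx = [core_genes.index(r) for r in regulators]
    wvec = np.array([gene_params.w[(r, gene)] for r in regulators])

    def f(t, x):
        u = float(wvec @ np.asarray(core_solution(t))[reg_idx]) if reg_idx else 0.0
        return -lam * x + kinetics.production(u, xi)

    times = np.asarray(times, float)
    sol = solve_ivp(f, (times[0], times[-1]), [x0], t_eval=times, rtol=rtol, atol=atol,
                    method="LSODA")
    if not sol.success:
        raise RuntimeError(f"driven simulation failed for {gene}: {sol.message}")
    return sol.y[0]


# ---------------------------------------------------------------------------
# Null models and validation statistics
# ---------------------------------------------------------------------------


@dataclass
class NullEnsemble:
    """Random structures from the prior, size- and sign-matched to a model."""

    structures: list
    signs: list
    seed: int
    costs: np.ndarray | None = None


def sample_null_structures(
    prior: NetworkStructure,
    n_edges: int,
    sign_counts: tuple[int, int],
    n_samples: int,
    seed: int = 0,
) -> NullEnsemble:
    """Draw structures with ``n_edges`` prior edges and a fixed sign multiset.

    Each sample takes ``n_edges`` uniformly without replacement from the
    prior's allowed edges and assigns signs by permuting the reference
    multiset ``sign_counts = (n_positive, n_negative)``.
    """
    n_pos, n_neg = sign_counts
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg != n_edges:
        raise ValueError("sign_counts must be non-negative and sum to n_edges")
    pool = list(prior.allowed_edges)
    if n_edges > len(pool):
        raise ValueError(f"n_edges={n_edges} exceeds the prior size {len(pool)}")
    rng = np.random.default_rng(seed)
    sign_multiset = np.array([1.0] * n_pos + [-1.0] * n_neg)
    structures, signs = [], []
    for _ in range(n_samples):
        pick = rng.choice(len(pool), size=n_edges, replace=False)
        edges = [pool[k] for k in pick]
        s = rng.permutation(sign_multiset)
        structures.append(prior.with_active(edges))
        signs.append({e: float(v) for e, v in zip(edges, s)})
    return NullEnsemble(structures, signs, int(seed))


def refit_fixed_signs(
    structure: NetworkStructure,
    signs: dict,
    timeseries: ExpressionTimeSeries,
    knockdowns: KnockdownDataset | None = None,
    kinetics="sigmoid",
    seed: int = 0,
    budget: int = 3000,
    popsize: int = DEFAULT_POPSIZE,
    dt: float = 0.1,
) -> FitResult:
    """Re-optimize magnitudes with every edge's sign held fixed.

    Positive edges search w in [0, 20], negative in [-20, 0]; degradation
    and production rates refit freely in [0, 20].  Used to transfer an
    inferred topology to new data, and to score null topologies.
    """
    ev = CostEvaluator(structure, timeseries, knockdowns, kinetics=kinetics, dt=dt)
    unsigned = [e for e in ev.free_edges if e not in signs]
    if unsigned:
        raise ValueError(f"active edges without a sign: {sorted(unsigned)}")
    bounds = list(ev.bounds)
    G = ev.n_genes
    for j, e in enumerate(ev.free_edges):
        bounds[2 * G + j] = (0.0, kin.W_BOUNDS[1]) if signs[e] > 0 else (kin.W_BOUNDS[0], 0.0)
    res = fit(ev, bounds, seed, budget=budget, popsize=popsize, vectorized=True)
    res.params = ev.params_from_vector(res.x)
    return res


def refit_null_ensemble(
    ensemble: NullEnsemble,
    timeseries,
    knockdowns=None,
    kinetics="sigmoid",
    seed: int = 0,
    budget: int = 3000,
    popsize: int = DEFAULT_POPSIZE,
    dt: float = 0.1,
) -> np.ndarray:
    """Refit every null structure (equal budgets) and record its cost."""
    costs = np.empty(len(ensemble.structures))
    for k, (s, sg) in enumerate(zip(ensemble.structures, ensemble.signs)):
        run_seed = int(
            np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31)
        )
        try:
            res = refit_fixed_signs(
                s, sg, timeseries, knockdowns, kinetics=kinetics,
                seed=run_seed, budget=budget, popsize=popsize, dt=dt,
            )
            costs[k] = res.best_cost
        except Exception as err:  # noqa: BLE001
            logger.warning("null refit %d failed: %s", k, err)
            costs[k] = np.inf
    ensemble.costs = costs
    return costs


def compare_to_null(model_cost, null_costs, level: str = "core",
                    correction: str = "none") -> dict:
    """Empirical comparison of model cost(s) against null-model costs.

    ``level='core'``: scalar cost vs a cost vector; empirical
    p = (#nulls with cost <= model) / n (so beating 994 of 1000 gives
    p = 0.006).  ``level='per_gene'``: ``model_cost`` is a vector over
    genes and ``null_costs`` a (n_genes, n_null) matrix; reports per-gene
    fractions of nulls beaten, the count of genes beating >= 95% of their
    nulls with a binomial test against the 5% expectation, and the fraction
    of genes beating their null mean with a binomial test against 1/2.
    Per-gene empirical p-values are reported uncorrected by default
    (typical null ensembles are too small to support stringent correction);
    ``correction='bh'`` adds Benjamini-Hochberg q-values.
    """
    if level == "core":
        null_costs = np.asarray(null_costs, float)
        if null_costs.size == 0:
            raise ValueError("null_costs must be non-empty")
        n = null_costs.size
        if n < 100:
            logger.warning("only %d null models: p-value resolution is 1/%d", n, n)
        p = float(np.sum(null_costs <= model_cost) / n)
        return {"p": p, "n_null": n, "n_beaten": int(np.sum(null_costs > model_cost))}
    if level != "per_gene":
        raise ValueError("level must be 'core' or 'per_gene'")

    model_cost = np.asarray(model_cost, float)
    null_costs = np.asarray(null_costs, float)
    if null_costs.ndim != 2 or null_costs.shape[0] != model_cost.size:
        raise ValueError("per-gene null_costs must be (n_genes, n_null)")
    n_genes, n_null = null_costs.shape
    frac_beaten = np.mean(null_costs > model_cost[:, None], axis=1)
    n_enriched = int(np.sum(frac_beaten >= 0.95))
    test_95 = stats.binomtest(n_enriched, n_genes, 0.05, alternative="greater")
    n_better_than_mean = int(np.sum(model_cost < null_costs.mean(axis=1)))
    test_mean = stats.binomtest(n_better_than_mean, n_genes, 0.5, alternative="greater")
    p_per_gene = 1.0 - frac_beaten  # fraction of nulls at or below the model
    out = {}
    if correction == "bh":
        out["q_per_gene"] = stats.false_discovery_control(
            np.clip(p_per_gene, 1 / (n_null + 1), 1.0), method="bh"
        )
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'bh'")
    return out | {
        "p_per_gene": p_per_gene,
        "frac_beaten": frac_beaten,
        "n_enriched_95": n_enriched,
        "expected_enriched_95": 0.05 * n_genes,
        "p_enriched_95": float(test_95.pvalue),
        "n_better_than_mean": n_better_than_mean,
        "frac_better_than_mean": n_better_than_mean / n_genes,
        "p_better_than_mean": float(test_mean.pvalue),
    }


def edge_validation_permutation(
    edge_scores: dict,
    removed_set,
    remaining_set,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Permutation test: are remaining edges' external scores higher?

    Statistic: mean score of remaining edges minus mean score of removed
    edges; the null shuffles the removed/remaining labels.  One-sided
    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    removed = [e for e in removed_set]
    remaining = [e for e in remaining_set]
    if not removed or not remaining:
        raise ValueError("both the removed and remaining sets must be non-empty")
    missing = [e for e in removed + remaining if e not in edge_scores]
    if missing:
        raise ValueError(f"edges without scores: {missing[:5]}")
    scores = np.array([edge_scores[e] for e in remaining + removed], dtype=float)
    n_rem = len(remaining)
    if np.ptp(scores) == 0:
        logger.warning("all edge scores identical; permutation test has no signal")
        return {"statistic": 0.0, "p": 1.0, "n_perm": n_perm}
    observed = scores[:n_rem].mean() - scores[n_rem:].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(scores)
        if perm[:n_rem].mean() - perm[n_rem:].mean() >= observed - 1e-12:
            count += 1
    return {"statistic": float(observed), "p": (1 + count) / (n_perm + 1), "n_perm": n_perm}


def predict_hidden_point(
    structure: NetworkStructure,
    timeseries: ExpressionTimeSeries,
    knockdowns: KnockdownDataset | None,
    hidden_points,
    kinetics="sigmoid",
    seed: int = 0,
    budget: int = 4000,
    popsize: int = DEFAULT_POPSIZE,
    dt: float = 0.1,
) -> dict:
    """Hidden-point prediction vs a linear-interpolation baseline.

    For each interior (gene, time) pair the point's cost weight is zeroed,
    the model is refit, and the hidden value is predicted by simulation;
    the baseline predicts by linear interpolation between the flanking
    observed time points.  Reports paired absolute residuals and a Wilcoxon
    signed-rank test (model < interpolation).
    """
    ts = timeseries.subset(structure.genes)
    times = ts.times
    rows = []
    for k, (gene, t) in enumerate(hidden_points):
        j = int(np.flatnonzero(np.isclose(times, t))[0]) if np.any(np.isclose(times, t)) else -1
        if j <= 0 or j >= times.size - 1:
            raise ValueError(
                f"hidden point ({gene}, {t}) is not an interior time point"
            )
        gi = ts.genes.index(gene)
        tau = np.ones_like(ts.y)
        tau[gi, j] = 0.0
        tau_kd = None
        if knockdowns is not None:
            tau_kd = np.ones_like(knockdowns.subset(structure.genes).responses)
        ev = CostEvaluator(
            structure, ts, knockdowns, kinetics=kinetics,
            weights=BootstrapWeights(tau, tau_kd), dt=dt,
        )
        run_seed = int(
            np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31)
        )
        res = fit(ev, ev.bounds, run_seed, budget=budget, popsize=popsize, vectorized=True)
        params = ev.params_from_vector(res.x)
        traj = integrate(structure, params, kinetics, ev.x0, times)
        y_true = ts.y[gi, j]
        y_model = traj.states[gi, j]
        w = (times[j] - times[j - 1]) / (times[j + 1] - times[j - 1])
        y_interp = (1 - w) * ts.y[gi, j - 1] + w * ts.y[gi, j + 1]
        rows.append(
            {
                "gene": gene,
                "time": float(t),
                "observed": float(y_true),
                "model": float(y_model),
                "interpolation": float(y_interp),
                "model_residual": abs(float(y_model - y_true)),
                "interp_residual": abs(float(y_interp - y_true)),
            }
        )
    table = pd.DataFrame(rows)
    diff = table["model_residual"] - table["interp_residual"]
    if len(table) >= 5 and np.any(diff != 0):
        p = float(stats.wilcoxon(table["model_residual"], table["interp_residual"],
                                 alternative="less").pvalue)
    else:
        p = float("nan")
    return {"table": table, "wilcoxon_p": p}
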