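"""Weighted least-squares objective over time-series and knockdown data.

The fit quality of a parameter set p is

    V(p) = sum_ij tau_ij (y_ij - yhat_ij(p))^2 / sigma_ij^2,

summed over every time-series point (replicate means, sigma estimated from
replicates) and every knockdown response point (sigma = 1).  All-ones
weights give the plain cost; uniform random weights give the bootstrap
variant.  Model output yhat comes from integrating the ODE system: the
wild-type system for time-series points, and one degradation-scaled system
per knockdown experiment compared against the wild type at the measurement
time (clipped log2 ratio, exactly like the data).

:class:`CostEvaluator` is the fast path: it evaluates V for a whole
population of parameter vectors at once using the batched exponential
integrator, which is what makes population-based search and combinatorial
backward elimination tractable.  :func:`cost` is the reference path through
the adaptive solver.
"""

from __future__ import annotations

import logging

import numpy as np

from . import kinetics as kin
from .data import BootstrapWeights, ExpressionTimeSeries, KnockdownDataset
from .kinetics import KineticParameters, get_kinetics
from .network import NetworkStructure
from .simulate import (
    IntegrationError,
    apply_knockdown,
    etd2rk_integrate,
    integrate,
    make_grid,
)

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.1  # fast-integrator step ceiling (hours)
_TINY = 1e-12


class CostEvaluator:
    """Population-vectorized objective for one jointly-modeled subsystem.

    Parameters
    ----------
    structure : NetworkStructure
        The subsystem to fit; every gene in it is a state variable.  For
        Step 1 this is the core subsystem.
    timeseries, knockdowns
        Data; internally re-ordered to the structure's gene order.
    kinetics : str or KineticsForm
    free_edges : sequence of edges, optional
        The active edges carrying a fitted weight (defaults to the
        structure's active edges, in canonical prior order).  Pruning
        shrinks this list; removed edges contribute exactly zero input.
    weights : BootstrapWeights, optional
    x0 : ndarray, optional
        Initial state; defaults to the replicate-mean expression at the
        first observed time point.
    dt : float
        Step ceiling of the fast integrator grid.

    The parameter vector layout is ``[lambda_1..G, xi_1..G, w_e1..eE]``.
    """

    def __init__(
        self,
        structure: NetworkStructure,
        timeseries: ExpressionTimeSeries,
        knockdowns: KnockdownDataset | None = None,
        kinetics="sigmoid",
        free_edges=None,
        weights: BootstrapWeights | None = None,
        x0: np.ndarray | None = None,
        dt: float = DEFAULT_DT,
    ):
        self.structure = structure
        self.kinetics = get_kinetics(kinetics)
        self.genes = structure.genes
        G = len(self.genes)
        self.ts = timeseries.subset(self.genes)
        self.kd = knockdowns.subset(self.genes) if knockdowns is not None else None
        if free_edges is None:
            order = structure.edge_index
            free_edges = sorted(structure.active_edges, key=order.__getitem__)
        self.free_edges = tuple(free_edges)
        for reg, tgt in self.free_edges:
            if reg not in self.genes or tgt not in self.genes:
                raise ValueError(f"edge {reg}->{tgt} leaves the subsystem")
        self.weights = weights if weights is not None else BootstrapWeights.ones(self.ts, self.kd)
        self.x0 = np.asarray(x0, float) if x0 is not None else self.ts.y[:, 0].copy()
        if self.x0.shape != (G,):
            raise ValueError("x0 must have one entry per subsystem gene")
        self.dt = float(dt)
        self._build_grid()

    # -- parameter packing -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_params(self) -> int:
        return 2 * self.n_genes + len(self.free_edges)

    @property
    def n_data_points(self) -> int:
        n = self.ts.n_points
        if self.kd is not None:
            n += self.kd.n_points
        return n

    @property
    def bounds(self) -> list[tuple[float, float]]:
        G = self.n_genes
        return (
            [kin.LAMBDA_BOUNDS] * G + [kin.XI_BOUNDS] * G + [kin.W_BOUNDS] * len(self.free_edges)
        )

    def params_from_vector(self, theta: np.ndarray) -> KineticParameters:
        theta = np.asarray(theta, float)
        G = self.n_genes
        w = dict(zip(self.free_edges, theta[2 * G:]))
        return KineticParameters(self.genes, theta[:G].copy(), theta[G:2 * G].copy(), w)

    def vector_from_params(self, params: KineticParameters) -> np.ndarray:
        G = self.n_genes
        theta = np.empty(self.n_params)
        theta[:G] = params.lambda_
        theta[G:2 * G] = params.xi
        theta[2 * G:] = [params.w.get(e, 0.0) for e in self.free_edges]
        return theta

    def with_free_edges(self, free_edges) -> "CostEvaluator":
        """Same data and settings, different fitted edge set (pruning step)."""
        ev = CostEvaluator.__new__(CostEvaluator)
        ev.__dict__.update(self.__dict__)
        ev.free_edges = tuple(free_edges)
        ev._build_index_arrays()
        return ev

    def with_weights(self, weights: BootstrapWeights) -> "CostEvaluator":
        ev = CostEvaluator.__new__(CostEvaluator)
        ev.__dict__.update(self.__dict__)
        ev.weights = weights
        return ev

    # -- fast evaluation ---------------------------------------------------

    def _build_grid(self):
        ts, kd = self.ts, self.kd
        t0 = float(ts.times[0])
        events = set(float(t) for t in ts.times)
        if kd is not None:
            events |= {float(s.measurement_time) for s in kd.specs}
        self._grid, event_idx = make_grid(t0, events, self.dt)
        rec = sorted(set(event_idx.values()))
        self._rec_idx = np.array(rec)
        pos = {i: k for k, i in enumerate(rec)}
        self._ts_pos = np.array([pos[event_idx[float(t)]] for t in ts.times])
        if kd is not None:
            self._kd_pos = np.array(
                [pos[event_idx[float(s.measurement_time)]] for s in kd.specs]
            )
            gi = {g: i for i, g in enumerate(self.genes)}
            scale = np.ones((1 + len(kd.specs), self.n_genes))
            for e, s in enumerate(kd.specs):
                scale[e + 1, gi[s.target_gene]] = 1.0 / s.fold_change
            self._lam_scale = scale
        else:
            self._kd_pos = None
            self._lam_scale = np.ones((1, self.n_genes))
        self._build_index_arrays()

    def _build_index_arrays(self):
        gi = {g: i for i, g in enumerate(self.genes)}
        self._w_rows = np.array([gi[t] for _, t in self.free_edges], dtype=int)
        self._w_cols = np.array([gi[r] for r, _ in self.free_edges], dtype=int)

    def warm_start(self) -> np.ndarray:
        """Data-driven initial parameter vector for the global search.

        The sign of an edge weight is read off the knockdown compendium —
        knocking a regulator down lowers its activating targets and raises
        its repressed ones, so sign(w) = -sign(response) — with magnitudes
        scaled by the response size.  Steady states are anchored at the
        last observed time point and production rates solved from the
        fixed-point relation xi = lambda x* / sigma(u*).  The result is a
        rough but structurally oriented start; without knockdown data the
        weights default to weak activation.
        """
        from scipy.special import expit

        G = self.n_genes
        gi = {g: i for i, g in enumerate(self.genes)}
        x_star = np.maximum(self.ts.y[:, -1], 1e-3)
        lam = np.full(G, 1.5)
        w = {}
        for r, g in self.free_edges:
            resp = 0.0
            if self.kd is not None:
                for k, spec in enumerate(self.kd.specs):
                    if spec.target_gene == r:
                        resp = self.kd.responses[k, gi[g]]
            if resp != 0.0:
                w[(r, g)] = -np.sign(resp) * min(8.0, max(1.0, 4.0 * abs(resp)))
            else:
                w[(r, g)] = 1.0
        u = np.zeros(G)
        for (r, g), v in w.items():
            u[gi[g]] += v * x_star[gi[r]]
        xi = np.clip(lam * x_star / expit(np.clip(u, -4.0, 4.0)), 1e-2, kin.XI_BOUNDS[1])
        theta = np.empty(self.n_params)
        theta[:G] = lam
        theta[G:2 * G] = xi
        theta[2 * G:] = [w[e] for e in self.free_edges]
        return theta

    def evaluate_population(self, X: np.ndarray) -> np.ndarray:
        """Cost for each row of ``X`` (shape (S, n_params))."""
        X = np.atleast_2d(np.asarray(X, float))
        S, G = X.shape[0], self.n_genes
        lam = np.clip(X[:, :G], 0.0, None)
        xi = X[:, G:2 * G]
        W = np.zeros((S, G, G))
        if len(self.free_edges):
            W[:, self._w_rows, self._w_cols] = X[:, 2 * G:]

        K = self._lam_scale.shape[0]
        lamK = lam[:, None, :] * self._lam_scale[None, :, :]
        x0 = np.broadcast_to(self.x0, (S, K, G)).copy()
        production = self.kinetics.production

        def prod_fn(state):
            u = np.einsum("sij,skj->ski", W, state)
            return production(u, xi[:, None, :])

        states = etd2rk_integrate(prod_fn, lamK, x0, self._grid, self._rec_idx)

        # time-series part: wild-type system (k = 0)
        yhat = states[self._ts_pos, :, 0, :]  # (T, S, G)
        resid = (self.ts.y.T[:, None, :] - yhat) / self.ts.sigma.T[:, None, :]
        tau = self.weights.tau_timeseries.T[:, None, :]
        V = np.einsum("tsg,tsg->s", tau * resid, resid)

        if self.kd is not None:
            tau_kd = self.weights.tau_knockdown
            for e in range(len(self.kd.specs)):
                p = self._kd_pos[e]
                x_wt = np.clip(states[p, :, 0, :], _TINY, None)
                x_kd = np.clip(states[p, :, e + 1, :], _TINY, None)
                lo, hi = self.kd.clip
                model = np.clip(np.log2(x_kd / x_wt), lo, hi)
                r = model - self.kd.responses[e][None, :]
                V += np.einsum("sg,sg->s", tau_kd[e][None, :] * r, r)

        V = np.where(np.isfinite(V), V, np.inf)
        return V

    def __call__(self, theta: np.ndarray) -> np.ndarray | float:
        """SciPy-compatible: accepts (n,) or (n, S), returns scalar or (S,)."""
        theta = np.asarray(theta, float)
        if theta.ndim == 1:
            return float(self.evaluate_population(theta[None, :])[0])
        return self.evaluate_population(theta.T)

    def cost_params(self, params: KineticParameters) -> float:
        """Fast-path cost of a decoded parameter set."""
        return float(self.evaluate_population(self.vector_from_params(params)[None, :])[0])


def cost(
    params: KineticParameters,
    structure: NetworkStructure,
    kinetics,
    timeseries: ExpressionTimeSeries,
    knockdowns: KnockdownDataset | None = None,
    weights: BootstrapWeights | None = None,
    x0: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> float:
    """Reference objective through the adaptive solver.

    Returns +inf (with a log record) when integration fails, so that
    optimization over ill-behaved parameter regions can proceed.
    """
    kinetics = get_kinetics(kinetics)
    ts = timeseries.subset(structure.genes)
    kd = knockdowns.subset(structure.genes) if knockdowns is not None else None
    if weights is None:
        weights = BootstrapWeights.ones(ts, kd)
    if x0 is None:
        x0 = ts.y[:, 0]
    try:
        traj = integrate(structure, params, kinetics, x0, ts.times, rtol=rtol, atol=atol)
    except IntegrationError as err:
        logger.warning("cost: integration failed (%s); returning inf", err)
        return float("inf")
    resid = (ts.y - traj.states) / ts.sigma
    V = float(np.sum(weights.tau_timeseries * resid**2))

    if kd is not None:
        t0 = float(ts.times[0])
        for e, spec in enumerate(kd.specs):
            try:
                T = spec.measurement_time
                times = np.array([t0, T]) if T > t0 else np.array([t0])
                wt = integrate(structure, params, kinetics, x0, times, rtol=rtol, atol=atol)
                kd_params = apply_knockdown(params, spec)
                kdt = integrate(structure, kd_params, kinetics, x0, times, rtol=rtol, atol=atol)
            except IntegrationError as err:
                logger.warning("cost: knockdown integration failed (%s)", err)
                return float("inf")
            x_wt = np.clip(wt.states[:, -1], _TINY, None)
            x_kd = np.clip(kdt.states[:, -1], _TINY, None)
            lo, hi = kd.clip
            model = np.clip(np.log2(x_kd / x_wt), lo, hi)
            r = model - kd.responses[e]
            V += float(np.sum(weights.tau_knockdown[e] * r**2))
    return V
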