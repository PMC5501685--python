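"""Backward-selection pruning and model assessment.

Pruning removes, at each step, the regulation weight whose elimination
(after a warm-started refit) increases the cost least.  The default
stopping rule is heuristic: stop before the first removal whose cost
increase exceeds ``c`` times the standard deviation of the current fit's
population costs (default c = 0.05), i.e. before the first increase that
stands out from optimizer stochasticity.  chi-square, AIC and BIC stops are
also available.  The full removal path is recorded past the stop point so
that consensus ranking across repeated runs (edges removed late are more
important) and any later cut remain possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import BootstrapWeights
from .kinetics import KineticParameters
from .network import Edge, NetworkStructure
from .objective import CostEvaluator
from .optimize import DEFAULT_POPSIZE, FitResult, _polish, fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriterion:
    """Stop-rule configuration for backward elimination.

    kind: 'heuristic_std' (cost increase vs c x population-cost std),
    'chi2' (keep removing while the refit cost stays below the chi-square
    critical value at df = number of data points), 'aic' or 'bic'
    (minimize V + penalty over the removal path).
    """

    kind: str = "heuristic_std"
    c: float = 0.05
    alpha: float = 0.05

    def __post_init__(self):
        if self.kind not in {"heuristic_std", "chi2", "aic", "bic", "cv"}:
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PruningTrace:
    """Ordered record of one backward-elimination run.

    ``removal_order[k]`` was removed at step k+1 with post-removal cost
    ``cost_at_step[k]``.  ``stop_index`` is the number of removals accepted
    by the stopping rule; removals past it are exploratory and excluded
    from ``final_structure``.
    """

    edge_universe: tuple[Edge, ...]
    removal_order: tuple[Edge, ...]
    cost_at_step: np.ndarray
    initial_cost: float
    stop_index: int
    final_structure: NetworkStructure
    params_at_stop: KineticParameters | None = None
    seed: int | None = None

    def __post_init__(self):
        self.cost_at_step = np.asarray(self.cost_at_step, dtype=float)
        if self.cost_at_step.shape != (len(self.removal_order),):
            raise ValueError("one cost per removal required")
        if not 0 <= self.stop_index <= len(self.removal_order):
            raise ValueError("stop_index out of range")

    def selection_rank(self, edge: Edge) -> int:
        """1-based removal position; never-removed edges get |edges| + 1."""
        try:
            return self.removal_order.index(edge) + 1
        except ValueError:
            return len(self.edge_universe) + 1

    def retained_edges(self) -> tuple[Edge, ...]:
        removed = set(self.removal_order[: self.stop_index])
        return tuple(e for e in self.edge_universe if e not in removed)


def stop_index_from_increases(increases, s: float, c: float) -> int:
    """First index whose cost increase exceeds ``c * s`` (heuristic rule).

    Returns the number of accepted removals, i.e. the rule stops *before*
    the offending removal.  If no increase trips the rule, all removals are
    accepted.
    """
    for k, inc in enumerate(increases):
        if inc > c * s:
            return k
    return len(list(increases))


def chi2_assess(V: float, df: int, alpha: float = 0.05) -> tuple[float, bool]:
    """Chi-square rejection test: critical value and whether V exceeds it.

    df is set to the number of data points; a model is rejected when its
    weighted residual sum V is larger than the (1 - alpha) quantile.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    critical = float(stats.chi2.ppf(1 - alpha, df=df))
    return critical, bool(V > critical)


def _step_seed(seed: int, step: int, cand: int) -> int:
    ss = np.random.SeedSequence(int(seed), spawn_key=(step, cand))
    return int(ss.generate_state(1)[0] % (2**31))


def backward_eliminate(
    evaluator: CostEvaluator,
    criterion: SelectionCriterion = SelectionCriterion(),
    seed: int = 0,
    initial_budget: int = 4000,
    initial_starts: int = 1,
    refit_budget: int = 800,
    popsize: int = DEFAULT_POPSIZE,
    refit_popsize: int = 24,
    refit_mode: str = "polish",
    refit_polish_iters: int = 100,
    initial_fit: FitResult | None = None,
    continue_past_stop: bool = True,
) -> tuple[PruningTrace, FitResult]:
    """Greedy backward elimination of regulation weights.

    At every step each remaining edge is tentatively fixed to zero and the
    model refit, warm-started from the incumbent with that weight dropped;
    the edge with the smallest refit cost is removed permanently, ties
    broken by lowest prior edge index.  Degradation and production rates
    are never pruned.

    Candidate refits use deterministic local refinement by default
    (``refit_mode='polish'``): candidate comparisons must resolve cost
    differences far smaller than the run-to-run spread of a stochastic
    global refit, and a common warm start keeps them on an equal footing.
    ``refit_mode='de'`` runs a short seeded global refit per candidate
    instead.  After each accepted removal the new incumbent is consolidated
    with a warm-started global refit at ``refit_budget`` so local-search
    bias cannot accumulate along the path.  Returns the trace and the
    initial full-model fit.
    """
    if criterion.kind == "cv":
        raise NotImplementedError(
            "cross-validation stopping is not implemented; use heuristic_std, "
            "chi2, aic or bic"
        )
    if refit_mode not in ("polish", "de"):
        raise ValueError("refit_mode must be 'polish' or 'de'")
    if not evaluator.free_edges:
        raise ValueError("nothing to prune: the evaluator has no free edges")

    lo = np.array([b[0] for b in evaluator.bounds])
    hi = np.array([b[1] for b in evaluator.bounds])
    if initial_fit is None:
        warm = evaluator.warm_start() if hasattr(evaluator, "warm_start") else None
        starts = [
            fit(
                evaluator, evaluator.bounds, _step_seed(seed, 0, k),
                budget=initial_budget, popsize=popsize, vectorized=True,
                warm_start=warm,
            )
            for k in range(max(1, initial_starts))
        ]
        initial_fit = min(starts, key=lambda r: r.best_cost)
    universe = tuple(evaluator.free_edges)
    n_points = evaluator.n_data_points
    chi2_crit = stats.chi2.ppf(1 - criterion.alpha, df=n_points)

    current = initial_fit
    current_params = evaluator.params_from_vector(initial_fit.x)
    remaining = list(universe)
    removal_order: list[Edge] = []
    cost_at_step: list[float] = []
    params_at_step: list[KineticParameters] = [current_params]
    stop_index: int | None = None

    step = 0
    while remaining:
        step += 1
        best = None
        for cand_i, edge in enumerate(remaining):
            free = [e for e in remaining if e != edge]
            ev = evaluator.with_free_edges(free)
            warm = ev.vector_from_params(current_params)
            if refit_mode == "polish":
                sub_lo = np.array([b[0] for b in ev.bounds])
                sub_hi = np.array([b[1] for b in ev.bounds])
                x, f, _ = _polish(ev, warm, sub_lo, sub_hi, True, refit_polish_iters)
            else:
                res = fit(
                    ev, ev.bounds, _step_seed(seed, step, cand_i),
                    budget=refit_budget, popsize=min(refit_popsize, refit_budget),
                    warm_start=warm, vectorized=True,
                    polish_top=1, polish_maxiter=60,
                )
                x, f = res.x, res.best_cost
            if best is None or f < best[3]:
                best = (edge, ev, x, f)
        edge, ev, x, f = best
        # consolidate the incumbent with a short seeded global refit
        res = fit(
            ev, ev.bounds, _step_seed(seed, step, 1_000_000),
            budget=max(refit_budget, 2 * refit_popsize),
            popsize=min(refit_popsize, refit_budget),
            warm_start=x, vectorized=True, polish_top=1, polish_maxiter=60,
        )
        step_cost = min(f, res.best_cost)
        step_x = x if f <= res.best_cost else res.x
        increase = step_cost - (cost_at_step[-1] if cost_at_step else initial_fit.best_cost)

        if stop_index is None:
            if criterion.kind == "heuristic_std" and increase > criterion.c * current.cost_std:
                stop_index = len(removal_order)
            elif criterion.kind == "chi2" and step_cost > chi2_crit:
                stop_index = len(removal_order)

        removal_order.append(edge)
        cost_at_step.append(step_cost)
        remaining.remove(edge)
        current = res
        current_params = ev.params_from_vector(step_x)
        params_at_step.append(current_params)
        if stop_index is not None and not continue_past_stop:
            break

    costs_path = np.concatenate(([initial_fit.best_cost], cost_at_step))
    if criterion.kind in ("aic", "bic"):
        k0 = 2 * evaluator.n_genes + len(universe)
        ks = k0 - np.arange(costs_path.size)
        penalty = 2.0 if criterion.kind == "aic" else np.log(n_points)
        stop_index = int(np.argmin(costs_path + penalty * ks))
    elif stop_index is None:
        stop_index = len(removal_order)

    retained = [e for e in universe if e not in set(removal_order[:stop_index])]
    base = evaluator.structure
    other_active = set(base.active_edges) - set(universe)
    final_structure = base.with_active(other_active | set(retained))
    trace = PruningTrace(
        edge_universe=universe,
        removal_order=tuple(removal_order),
        cost_at_step=np.array(cost_at_step),
        initial_cost=float(initial_fit.best_cost),
        stop_index=stop_index,
        final_structure=final_structure,
        params_at_stop=params_at_step[stop_index],
        seed=int(seed),
    )
    return trace, initial_fit


def consensus_rank(traces, rank_threshold: float) -> pd.DataFrame:
    """Median selection rank per edge across repeated pruning runs.

    An edge's rank in one trace is its 1-based removal position; edges never
    removed get the sentinel |edges| + 1 (maximally important).  Edges whose
    median rank exceeds ``rank_threshold`` are included in the consensus
    model.  The result is permutation-invariant in the trace order.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("consensus ranking needs >= 2 traces")
    universe = set(traces[0].edge_universe)
    for t in traces[1:]:
        if set(t.edge_universe) != universe:
            raise ValueError("traces cover different edge universes")
    edges = sorted(universe)
    ranks = np.array([[t.selection_rank(e) for t in traces] for e in edges])
    med = np.median(ranks, axis=1)
    return pd.DataFrame(
        {
            "regulator": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "median_rank": med,
            "included": med > rank_threshold,
        },
        index=pd.Index([f"{r}->{t}" for r, t in edges], name="edge"),
    )


def bootstrap_sensitivity(
    evaluator: CostEvaluator,
    n_boot: int,
    criterion: SelectionCriterion = SelectionCriterion(),
    seed: int = 0,
    **eliminate_kwargs,
) -> list[dict]:
    """Re-run pruning under uniform random per-point cost weights.

    For each replicate an independent tau ~ U[0, 1] is drawn per data point
    (time-series and knockdown alike) and backward elimination is repeated
    under the weighted cost.  Per-replicate failures are returned flagged,
    never raised.  Returns a list of dicts with keys ``trace``, ``weights``,
    ``error``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    out = []
    for b in range(n_boot):
        ss = np.random.SeedSequence(int(seed), spawn_key=(b,))
        w_seed, run_seed = [int(s % (2**31)) for s in ss.generate_state(2)]
        weights = BootstrapWeights.sample(
            evaluator.ts, evaluator.kd, np.random.default_rng(w_seed)
        )
        ev = evaluator.with_weights(weights)
        try:
            trace, _ = backward_eliminate(
                ev, criterion=criterion, seed=run_seed, **eliminate_kwargs
            )
            out.append({"trace": trace, "weights": weights, "error": None})
        except Exception as err:  # noqa: BLE001 - flagged, not fatal
            logger.warning("bootstrap replicate %d failed: %s", b, err)
            out.append({"trace": None, "weights": weights, "error": str(err)})
    return out


def rank_variability(traces) -> float:
    """Mean per-edge standard deviation of selection ranks across traces."""
    traces = list(traces)
    edges = sorted(set(traces[0].edge_universe))
    ranks = np.array([[t.selection_rank(e) for t in traces] for e in edges])
    return float(ranks.std(axis=1).mean())
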