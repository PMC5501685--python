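"""Datasets: expression time series, knockdown responses, bootstrap weights.

The fitted quantity per gene and time point is the replicate mean; replicate
spread enters only through the standard-deviation matrix that scales the
least-squares residuals.  Knockdown responses are clipped log2 fold changes
with their standard deviation fixed at 1 (too few replicates to estimate
one, and this keeps the two data types' cost contributions on comparable
scales).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import CLIP_RANGE, KnockdownSpec

logger = logging.getLogger(__name__)

SIGMA_FLOOR_FRAC = 0.05  # default sigma floor: 5% of the gene's dynamic range


@dataclass
class ExpressionTimeSeries:
    """Replicate-mean expression with per-point standard deviations.

    ``y[i, j]`` is the replicate mean of gene ``genes[i]`` at ``times[j]``;
    ``sigma`` has the same shape and is strictly positive (floored).
    ``replicates`` optionally keeps the raw values: one (n_genes, n_rep)
    array per time point, with possibly different replicate counts per time
    (ragged designs are accepted).
    """

    genes: tuple[str, ...]
    times: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    replicates: list | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        G, T = len(self.genes), self.times.size
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.y.shape != (G, T) or self.sigma.shape != (G, T):
            raise ValueError("y and sigma must be (n_genes, n_times)")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite expression values")
        if not np.all(self.sigma > 0):
            raise ValueError("sigma must be strictly positive everywhere")
        if self.replicates is not None:
            if len(self.replicates) != T:
                raise ValueError("one replicate block per time point required")
            self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
            for r in self.replicates:
                if r.ndim != 2 or r.shape[0] != G:
                    raise ValueError("replicate blocks must be (n_genes, n_rep)")

    @classmethod
    def from_replicates(
        cls,
        genes,
        times,
        replicates,
        sigma_mode: str = "pooled",
        floor_frac: float = SIGMA_FLOOR_FRAC,
    ) -> "ExpressionTimeSeries":
        """Build the series from raw replicates, estimating sigma."""
        genes = tuple(genes)
        replicates = [np.asarray(r, dtype=float) for r in replicates]
        y = np.column_stack([r.mean(axis=1) for r in replicates])
        ts = cls(genes, np.asarray(times, float), y, np.ones_like(y), replicates)
        ts.sigma = estimate_sigma(ts, mode=sigma_mode, floor_frac=floor_frac)
        return ts

    def subset(self, genes) -> "ExpressionTimeSeries":
        """Restriction to a gene subset (order follows the argument)."""
        genes = tuple(genes)
        idx = [self.genes.index(g) for g in genes]
        reps = [r[idx] for r in self.replicates] if self.replicates else None
        return ExpressionTimeSeries(
            genes, self.times.copy(), self.y[idx], self.sigma[idx], reps
        )

    @property
    def n_points(self) -> int:
        """Number of fitted data points (genes x time points)."""
        return self.y.size


def estimate_sigma(
    timeseries: ExpressionTimeSeries,
    mode: str = "pooled",
    floor_frac: float = SIGMA_FLOOR_FRAC,
) -> np.ndarray:
    """Standard-deviation matrix estimated from replicates.

    ``mode='pooled'`` (default): one sigma per gene, pooling squared
    replicate deviations across all time points of that gene —
    ``sqrt(sum_t sum_r (y_rt - ybar_t)^2 / sum_t (n_t - 1))`` — broadcast to
    every time point.  Robust at the 3-4 replicates typical of microarray
    time courses.  ``mode='per_point'`` estimates each (gene, time) cell
    separately, falling back to the pooled value where a time point has a
    single replicate.

    Every value is floored at ``floor_frac`` times the gene's dynamic range
    (with a tiny absolute floor for exactly constant genes) so the weighted
    cost can never divide by zero.
    """
    ts = timeseries
    if ts.replicates is None:
        raise ValueError("sigma estimation requires raw replicates")
    n_reps = np.array([r.shape[1] for r in ts.replicates])
    if np.all(n_reps < 2):
        raise ValueError(
            "no time point has >= 2 replicates; supply an explicit sigma matrix"
        )

    G, T = ts.y.shape
    ss = np.zeros(G)
    dof = 0
    per_point = np.full((G, T), np.nan)
    for j, r in enumerate(ts.replicates):
        if r.shape[1] < 2:
            continue
        dev = r - r.mean(axis=1, keepdims=True)
        ss += (dev**2).sum(axis=1)
        dof += r.shape[1] - 1
        per_point[:, j] = r.std(axis=1, ddof=1)
    pooled = np.sqrt(ss / dof)

    if mode == "pooled":
        sigma = np.repeat(pooled[:, None], T, axis=1)
    elif mode == "per_point":
        sigma = np.where(np.isnan(per_point), pooled[:, None], per_point)
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")

    gene_range = ts.y.max(axis=1) - ts.y.min(axis=1)
    floor = np.maximum(floor_frac * gene_range, 1e-9)
    n_floored = int((sigma < floor[:, None]).any(axis=1).sum())
    if n_floored:
        logger.info("sigma floored for %d genes", n_floored)
    return np.maximum(sigma, floor[:, None])


def responsiveness_filter(
    timeseries: ExpressionTimeSeries, alpha: float = 0.05, return_stats: bool = False
):
    """Keep genes whose time course rejects the white-noise null model.

    Under the null, a gene's expression is constant at its mean and the
    scaled residual sum ``sum_j (y_j - ybar)^2 / sigma_j^2`` is chi-square
    with df equal to the number of time points.  A gene is kept when its
    residual exceeds the (1 - alpha) critical value, i.e. when constancy is
    rejected.  Returns the kept gene list (and per-gene statistics when
    ``return_stats`` is set).
    """
    ts = timeseries
    if ts.times.size < 2:
        raise ValueError("responsiveness filter needs >= 2 time points")
    resid = ((ts.y - ts.y.mean(axis=1, keepdims=True)) ** 2 / ts.sigma**2).sum(axis=1)
    crit = stats.chi2.ppf(1 - alpha, df=ts.times.size)
    kept = [g for g, r in zip(ts.genes, resid) if r > crit]
    if not kept:
        logger.warning("responsiveness filter removed every gene")
    if return_stats:
        return kept, {"residual": dict(zip(ts.genes, resid)), "critical": float(crit)}
    return kept


@dataclass
class KnockdownDataset:
    """Measured per-gene responses to a set of knockdown experiments.

    ``responses[e, i]`` is the clipped log2 fold change of gene
    ``genes[i]`` in experiment ``specs[e]``.  sigma is identically 1.
    """

    genes: tuple[str, ...]
    specs: tuple[KnockdownSpec, ...]
    responses: np.ndarray
    clip: tuple[float, float] = CLIP_RANGE

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != (len(self.specs), len(self.genes)):
            raise ValueError("responses must be (n_experiments, n_genes)")
        lo, hi = self.clip
        if np.any(self.responses < lo - 1e-12) or np.any(self.responses > hi + 1e-12):
            raise ValueError(f"responses outside clip range [{lo}, {hi}]")

    @property
    def sigma(self) -> float:
        return 1.0

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(s.target_gene for s in self.specs)

    @property
    def n_points(self) -> int:
        return self.responses.size

    def subset(self, genes) -> "KnockdownDataset":
        genes = tuple(genes)
        idx = [self.genes.index(g) for g in genes]
        return KnockdownDataset(genes, self.specs, self.responses[:, idx], self.clip)


@dataclass
class BootstrapWeights:
    """Per-data-point cost weights tau in [0, 1].

    All-ones weights reproduce the plain weighted least squares; uniformly
    resampled weights probe how sensitive model selection is to the
    influence of individual data points.
    """

    tau_timeseries: np.ndarray
    tau_knockdown: np.ndarray | None = None

    def __post_init__(self):
        self.tau_timeseries = np.asarray(self.tau_timeseries, dtype=float)
        for tau in (self.tau_timeseries, self.tau_knockdown):
            if tau is not None and (np.any(tau < 0) or np.any(tau > 1)):
                raise ValueError("weights must lie in [0, 1]")
        if self.tau_knockdown is not None:
            self.tau_knockdown = np.asarray(self.tau_knockdown, dtype=float)

    @classmethod
    def ones(cls, timeseries: ExpressionTimeSeries, knockdowns: KnockdownDataset | None):
        tau_kd = None if knockdowns is None else np.ones_like(knockdowns.responses)
        return cls(np.ones_like(timeseries.y), tau_kd)

    @classmethod
    def sample(
        cls,
        timeseries: ExpressionTimeSeries,
        knockdowns: KnockdownDataset | None,
        rng: np.random.Generator,
    ):
        """Independent Uniform[0, 1] weight per time-series and knockdown point."""
        tau_ts = rng.uniform(size=timeseries.y.shape)
        tau_kd = None if knockdowns is None else rng.uniform(size=knockdowns.responses.shape)
        return cls(tau_ts, tau_kd)
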