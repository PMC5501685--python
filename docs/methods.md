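# Methods

## Model

Each modeled gene i evolves as

    dx_i/dt = −λ_i x_i + ξ_i σ(Σ_j w_ij x_j),      σ(u) = 1/(1+e^−u)

with first-order decay (rate λ_i, 1/h), maximal transcription ξ_i
(expression·1/h), and signed weights w_ij over the gene's *active*
in-edges.  The production term lies strictly in (0, ξ_i) for finite
inputs, so for positive rates every trajectory is bounded by
max_i ξ_i/λ_i plus the initial condition; the system is integrable for any
parameter draw inside the search box (λ, ξ ∈ [0, 20], w ∈ [−20, 20]).
A linear form (−λx + Wx + ξ, with ξ as basal production sharing the
[0, 20] bound) and user-supplied production functions plug into the same
machinery.  Degradation is always separate from regulation: a self-edge
w_ii, when present in the prior, adds regulatory input but never replaces
−λ_i x_i.

Genes split into a *core* (jointly modeled TFs, feedback allowed) and
*peripheral* genes (regulated by core genes only, no feedback, no
peripheral–peripheral edges).  All candidate edges come from a prior list;
inference deactivates edges but never invents them.  Externally genes are
strings; internally they map to dense indices in a fixed order (core
first), which is what makes genome-scale vectorization possible.

## Data model and objective

Time-series data are replicate means y_ij with standard deviations σ_ij
estimated from replicates, pooled per gene across all time points
(per-(gene,time) estimation is available; pooling is the default because
3–4 replicates per point make cellwise estimates unstable).  σ is floored
at 5% of the gene's dynamic range (configurable) to keep the weighted
residuals finite for near-constant genes.  Knockdown responses are log2
fold changes versus control, clipped to [−2, 2], with σ fixed at 1; that
convention also keeps the two data types' cost contributions comparable.

The objective is V(p) = Σ τ_ij (y_ij − ŷ_ij(p))²/σ_ij² over both data
types, with τ ≡ 1 normally and τ ~ U[0,1] per point in bootstrap
reweighting.  The model output for a knockdown experiment is the clipped
log2 ratio of the perturbed to the unperturbed simulation at the
experiment's measurement time, both integrated from the same initial
state; the perturbation itself scales the target's decay,
λ̃ = λ·(x/x̃) = λ/fold-change.  The initial state is the replicate-mean
expression at the first observed time point — the simplest data-anchored
convention; simulating knockdowns from a pre-equilibrated state instead
would be a one-line change but is not what the fitted trajectories use.

Genes whose time course is indistinguishable from white noise around a
constant are flagged by the responsiveness filter: the gene is kept when
Σ_j (y_ij − ȳ_i)²/σ_ij² exceeds the χ² 0.95-quantile at df = number of
time points (the test rejects constancy, i.e. large residuals mean
*responsive*).

## Numerics

Two integration paths coexist deliberately:

* the **reference path** — SciPy's adaptive, stiff-capable LSODA at
  rtol 1e-6 / atol 1e-8 — is used for every reported trajectory, the
  public `integrate`, knockdown responses, and the assembled model;
* the **fast path** is a second-order exponential integrator (ETD2RK)
  exploiting the decay/production split: decay is treated exactly (stable
  for any λ ≥ 0, exact in the λ→0 limit via series coefficients), the
  production term to second order.  It advances the whole optimizer
  population and all knockdown variants in lock-step on a grid with step
  ≤ 0.1 h that lands exactly on every observation time.  Against the
  reference it agrees to ~1e-5 relative cost near plausible parameters and
  a few percent in the stiffest corners of the box, which is ample for
  ranking candidate fits; final reported costs come from the same fast
  evaluator and are verified against the reference in the tests.

For peripheral genes the core trajectories are precomputed once (reference
solver, sampled on the fast grid) and the scalar gene ODE with known
time-varying forcing is advanced by the exact exponential-trapezoidal
recurrence — per-gene fits then cost milliseconds.

## Optimization

All fitting is a seeded memetic differential evolution: best/1/bin with
dithered mutation factor U(0.5, 1), crossover 0.9, box clipping, and —
after the DE budget is spent — L-BFGS-B polishing of the few best distinct
members, with the forward-difference gradient evaluated in a single
vectorized cost call.  The ODE least-squares landscape is rugged (sigmoid
saturation, sign-flip near-symmetries in feedback loops); pure DE at desk
budgets stalls in poor basins and pure multistart local search hits the
right basin too rarely, while the combination is reliable.  Two further
ingredients matter:

* **Data-driven warm start.** Knocking down a regulator lowers its
  activated targets and raises its repressed ones, so the sign of w_rg is
  read off the knockdown response matrix (magnitude scaled by the response
  size), steady states are anchored at the last time point, and ξ is
  solved from the fixed-point relation ξ = λx*/σ(u*).  This start is
  injected into the initial population and polished first; it places the
  search in the correct sign orthant, which is the dominant failure mode
  otherwise.
* **Determinism.** Every stochastic element derives from integer seeds via
  `SeedSequence` (spawn keys per run/step/candidate, values kept below
  2^31); identical seeds and inputs give bit-identical results regardless
  of worker count, and parallel maps preserve run-index order.

Defaults for the core step: population 80, initial budget 20,000
evaluations × 2 starts, consolidation refits 2,000.  Peripheral genes use
population 24 and budget 1,500 — the driven problems are 3–6 dimensional.

## Model selection

Backward elimination removes, at each step, the active weight whose
elimination increases the refit cost least (ties broken by prior edge
index).  Candidate refits are *deterministic polish* from the incumbent
with the candidate weight zeroed: candidate comparisons must resolve cost
differences well below the run-to-run spread of a stochastic refit, and a
shared warm start puts all candidates on an equal footing.  After each
accepted removal the incumbent is consolidated by a short seeded global
refit so local-search bias cannot accumulate along the path.  λ and ξ are
never pruned — the model form requires them.

Stopping rules: the default heuristic stops before the first removal whose
cost increase exceeds c × the standard deviation of the current fit's
final population costs (c = 0.05); a χ² rule removes while the refit cost
stays below the critical value at df = number of data points; AIC
(V + 2k) and BIC (V + k ln n) pick the argmin along the recorded path.
The full removal path is always recorded past the stop point, so
consensus ranking — median 1-based removal position across repeated runs,
never-removed edges getting the sentinel |edges|+1, inclusion above a
rank threshold — and any later cut remain possible.  A cross-validation
stop is declared but not implemented: no split protocol would be canonical
for 6-point time courses, and silently inventing one seemed worse than
refusing.

χ² assessment of any fitted model uses df = number of data points and
α = 0.05.  Because the objective compares replicate *means* against
replicate-based σ, the expected V at the truth is roughly n/r for r
replicates, comfortably below the df = n critical value — the test is
conservative by construction, which matches how it is used (rejecting
gross misfit, not calibrating coverage).

## Validation statistics

* **Null ensembles**: structures drawn uniformly without replacement from
  the prior with the same edge count as the reference model and the
  reference's sign multiset permuted onto them; each is refit with signs
  fixed (w restricted to [0,20] or [−20,0]) at the same budget as the
  reference refit.  Core-level empirical p uses the add-nothing convention
  p = #{null ≤ model}/n.  Per-gene summaries report the fraction of genes
  beating ≥95% of their nulls (binomial test against 5%) and the fraction
  beating their null mean (binomial test against 1/2); per-gene p-values
  are reported uncorrected by default with an optional Benjamini–Hochberg
  adjustment (``correction='bh'``) — at 100 nulls per gene the resolution
  does not support stringent correction, so the option is off by default.
* **Edge validation**: for external per-edge scores, the statistic is
  mean(score | retained) − mean(score | removed) with a label-shuffling
  null and the add-one convention p = (1 + #{perm ≥ obs})/(n_perm + 1).
* **Hidden-point prediction**: an interior observation's weight is zeroed,
  the model refit, and the simulated value compared against linear
  interpolation between the flanking observations (Wilcoxon signed-rank
  on paired absolute residuals).  Boundary points are rejected — they have
  no interpolation baseline.

## Synthetic truths

The generator emulates a differentiation experiment: a random core
digraph at the requested density (redrawn until it contains a feedback
cycle when the edge budget permits), peripheral in-edges from the core
only, replicated Gaussian-noise measurements (sd = 5% of each gene's
trajectory range by default, 6 time points over 8 h × 3 replicates),
knockdowns of every core TF with fold changes U[0.2, 0.6] measured at the
final time point (log2 responses get sd-0.1 noise before clipping), and a
prior contaminated with decoy edges (45% of the prior by default).

Truth parameters are constructed for *identifiability*, not just drawn:
steady-state targets x* ~ U[0.15, 0.6] come first; signed weights
(magnitudes U[1, 10]) are resampled until the summed input at steady state
lies in the sigmoid's responsive range (u* ∈ [−1.5, 2.5]) and every edge
contributes at least 1.2 input units; ξ is then solved from
ξ = λx*/σ(u*) so x* is an exact fixed point, and trajectories start at
10–30% of x*.  Without these constraints most drawn systems park their
sigmoids in saturation, where removing a true edge is absorbed by a ξ
adjustment and *no* method could recover the structure — a recovery
benchmark on such truths measures nothing.  λ ~ U[0.5, 5] throughout.

What the generator does **not** emulate: platform-specific noise
(probe effects, saturation, batch structure), unmodeled regulators,
indirect effects collapsed into single edges, and mRNA/protein
discrepancies.  Passing recovery tests therefore demonstrates that the
estimation and pruning machinery works when the model class contains the
truth — not that real prior networks are this benign.

## Problem sizes and known limitations

The shipped studies run on one CPU: the recovery study uses five truths of
5 TFs (8 true edges, 7 decoys) with and without knockdown data; the
pruning oracle uses 3 TFs and 2+2 edges with exhaustive subset
enumeration; decoupling and null comparisons use 3-TF cores with a few
peripheral genes and 50-member null ensembles.  These sizes exercise every
code path; the same interfaces scale to hundreds of peripheral genes per
worker-hour since Step 2 is linear in gene count.

Known limitations: the heuristic stop rule inherits its scale from the
optimizer population's cost spread, so it is twitchy when the population
has collapsed (the recorded full path and the χ²/AIC/BIC alternatives are
the mitigation); recovered networks on saturated regimes are
unidentifiable in principle; and the empirical-p machinery needs null
ensembles of ~1/p members, so small ensembles bound the attainable
significance.
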