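# Methods

This note documents the models, numerical choices and limitations behind
`couplingswarm`, in the order the pipeline runs them.

## The scoring metric

The score of a prediction vector over a record selection is the mean,
over the coupling types present in that selection, of the natural log of
the per-type mean absolute error (Hz). Properties the implementation
guarantees and the tests assert:

- **Scale equivariance**: multiplying every absolute error by c > 0 adds
  exactly ln c to the score.
- **Type balance**: a 10% relative MAE improvement in any one of the 8
  types moves the score by ln(0.9)/8, independent of the type's abundance
  or value scale.
- **Exponential transform**: `geometric_mean_error = exp(score)` is the
  geometric mean of the per-type MAEs; score differences are log accuracy
  folds (`accuracy_ratio`).

**MAE floor.** Per-type MAE is floored at 1e-9 Hz before the log, so a
perfect submission scores ln(1e-9) ≈ −20.72 per type rather than −∞.
The floor only matters for near-perfect synthetic submissions; it keeps
the ensemble optimizer's objective finite when a constituent reproduces
the truth exactly.

**Leaderboards.** A team's entry is its best (lowest) submission score on
the selected split; ties break by earlier timestamp, then team id.

## Meta-ensemble fitting

The ME prediction is a convex combination (non-negative weights summing
to 1) of the pooled submissions' predictions, ranked best-first; rank k
is the best rank still included. Choices:

- **Objective**: the grouped log-MAE score of the combined predictions on
  the fitting half — the quantity the leaderboard itself measures. The
  per-type variant decomposes into T independent *convex* MAE
  minimizations (each type's weights affect only its own log term); the
  global variant is piecewise-smooth and non-convex, hence multi-start.
- **Fitting/evaluation halves**: a seeded random 50/50 split of the test
  records, stratified by coupling type so every type appears in both
  halves. The public/private split is deliberately not reused here: the
  fitting half plays the role of "data the ensembler may see", which is a
  different axis from leaderboard visibility.
- **Optimizer**: SLSQP with analytic subgradients under bounds and the
  equality constraint, multi-started from the uniform point and the
  best-scoring vertices; *every* vertex is evaluated as a candidate and
  the best candidate overall is returned. This construction guarantees
  vertex dominance (the fitted ME never scores worse on the fitting half
  than any single constituent) regardless of optimizer convergence.
  Convergence tolerance 1e-10, iteration cap 10,000. The k-sweep
  additionally warm-starts each k from the previous k's solution
  re-normalized over the remaining ranks.
- **Oracle**: `grid_search_simplex` enumerates the full 0.001-step
  simplex lattice (exact brute force, vectorized and chunked); the test
  suite checks the optimizer is at least as good as the lattice optimum
  to 1e-6 in score at 2–4 constituents. The lattice itself is quantized,
  so the optimizer may legitimately be *better* than the grid; the check
  is one-sided.
- **Ranking of constituents**: by individual score on the fitting half.
  An externally supplied rank order (e.g. a replayed leaderboard) can be
  passed instead.
- **Median combiner**: unweighted per-record median; at even counts the
  lower middle value is taken (deterministic). No weights are optimized
  in median mode.
- **Contributors**: constituents with weight strictly greater than a
  threshold (default 0.01); in per-type mode, greater than the threshold
  for at least one type.

## Residual-correlation analysis

Similarity is computed on **residuals** (prediction − truth), not raw
predictions: raw predictions of competent models are dominated by the
shared truth signal and correlate near 1 for every pair, which would
erase all structure. Pearson correlation is the default (Spearman-like
alternatives can be computed by pre-ranking the residuals upstream);
zero-variance residual vectors (perfect submissions) are rejected as
degenerate rather than silently assigned a correlation.

Clustering is scipy agglomerative linkage on the distance 1 − r, average
linkage by default (single/complete configurable); the leaf order is
scipy's deterministic dendrogram order, so relabelling teams permutes
results equivariantly up to subtree orientation. `outlier_score` ranks
teams by mean off-diagonal correlation, ascending — the "distinct
architecture" signature: a team whose errors look like no one else's.

## Leaderboard dynamics

`running_best` is the cumulative minimum of score over time (stable
order: timestamp, then team id). Before fitting, the trace is resampled
to a uniform daily grid with last-value-carried-forward, so bursts of
dense submissions do not dominate the least-squares objective; raw event
times can be fitted by passing `resample_step_days=None`.

The bi-exponential `A·exp(−t/τ₁) + B·exp(−t/τ₂) + C` is fitted
separably: for each ordered pair (τ₁ > τ₂) on a 25-point logarithmic
grid over [0.1, 200] days, the linear parameters (A, B, C) are solved by
least squares; the best grid point seeds a joint bounded
Levenberg–Marquardt refinement of all five parameters (tolerances 1e-14).
Sums of exponentials are notoriously initialization-sensitive; the
separable grid makes the fit deterministic and seed-independent. After
fitting, τ₁ ≥ τ₂ is enforced by swapping the (amplitude, τ) pairs.
Degenerate cases are reported honestly rather than disguised:

- a constant trace returns A = B = 0, C = the constant, τs = NaN, and
  `identifiable = False`;
- a single-exponential trace fits as two equal τs with an arbitrary
  amplitude split; when the fitted τs agree within 0.1% the amplitudes
  are merged into the slow term (canonical form A = total, B = 0);
- if the joint refinement fails to improve on the grid solution, the grid
  solution is returned with `converged = False` (monotone acceptance).

`phase_summary` evaluates the fitted curve at a phase boundary and
reports per-phase score change, the implied accuracy factor exp(−Δ), and
the dominant time constant (the exponential term losing the most
amplitude inside the phase).

## The synthetic competition generator

The generator's defaults are the study conditions the analyses are
validated under; they are fixed once, not tuned per analysis.

**Truth table.** Eight coupling types with per-type normal value
distributions (location ± scale, Hz). The default abundances pin the
most frequent type (3JHC) at 33.56× the least frequent (1JHN) — the
extreme count imbalance characteristic of exhaustive coupling enumeration
over small organic molecules — with the remaining six relative weights
interpolated between those anchors, and locations/scales set to typical
magnitudes for each bond-count/nucleus class (e.g. one-bond CH couplings
near +94 Hz with an 18 Hz spread; three-bond HN couplings near +0.9 Hz
with a 1.3 Hz spread). These six weights and all locations/scales are
package defaults, declared rather than derived. Per-type record counts,
the 65/35 molecule-level train/test split, and the 29/71 record-level
public/private split are all exact under largest-remainder rounding, so
split-exactness holds at any problem size.

**Submissions.** Team j in strategy cluster c with skill factor s_j
predicts record i of type τ at time t as

```
truth_i + s_j · envelope(t) · σ_τ · ( √ρ · Z_{c,i} + √(1−ρ) · ε )
```

with Z a cluster-shared standard normal fixed per (cluster, record) and ε
idiosyncratic per (team, record, submission). Consequences used as planted
ground truth: marginal per-type MAE → s_j · envelope · σ_τ · √(2/π);
residual correlation → ρ within a cluster, 0 across clusters. Default
error scale σ_τ is 10% of the type's value spread; default skills are
lognormal (σ = 0.5) draws from a seeded substream.

**Improvement envelope.** The error scale is multiplied by
`envelope(t) = exp(s(t) − s(0))`, where s is the configured bi-exponential
progress curve. Because the score is the log of error, this makes a
population's best-score trace approximately bi-exponential in score
space — approximately, not exactly (the running best is a minimum over
noisy teams), and the dynamics module never assumes exactness. The
envelope is 1 at t = 0 by construction.

**Determinism.** All randomness flows from one master seed through named
substreams (dataset, cluster-noise, idiosyncratic, timestamps, skills);
identical configs give byte-identical datasets and submissions.
Timestamps are uniform over the competition duration per team, sorted.

**What it does not emulate.** No molecular geometry (atom indices are
synthetic labels; no analysis in scope consumes coordinates), no
per-molecule difficulty structure, no heavy-tailed or type-correlated
team errors, no strategic submission timing, and no leaderboard-feedback
adaptation. Passing tests therefore demonstrate correctness of the
*analyses* under the planted statistical structure, not fidelity of any
particular real competition's error geometry.

## Problem sizes

Tests and the examples run at desk scale: hundreds to a few thousand
molecules, 4–20 teams, chosen so planted-structure assertions have
comfortable statistical margins (e.g. correlation assertions at ≥ 5,000
records where the sampling error of r is below 0.015; MAE calibration at
≥ 45,000 records per type where the sampling error of the MAE is ~0.5%).
The ensemble held-out-benefit property is asserted over 20 seeded
populations with ≥ 10,000 evaluation records each.

## Known limitations

- The global simplex objective is non-convex; multi-start with analytic
  subgradients finds the lattice optimum in all tested configurations,
  but global optimality is not certified for large pools.
- Pearson residual correlation measures linear co-error only; two teams
  with identical error *magnitude* structure but opposite signs appear
  anti-correlated, not similar.
- Bi-exponential τ estimates are ill-conditioned when the two time
  constants are within a factor of ~3 of each other or when the trace
  span is short relative to τ₁; the `converged`/`identifiable` flags and
  rss should be inspected before interpreting parameters.
- The public/private stability of rankings depends on record counts; at
  very small synthetic sizes the two leaderboards can legitimately
  disagree.
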