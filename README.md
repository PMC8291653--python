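# couplingswarm

Meta-analysis toolkit for crowdsourced NMR scalar-coupling prediction
competitions.

When hundreds of teams compete to predict the same molecular property, the
submission pool itself becomes a scientific object: how fast does the
field improve, how redundant are the top models, and how much accuracy can
be recovered by stacking the field's predictions? `couplingswarm`
implements that analysis pipeline for competitions over the standard eight
scalar-coupling categories (1JHC, 1JHN, 2JHH, 2JHC, 2JHN, 3JHH, 3JHC,
3JHN), together with a seeded synthetic-competition generator so every
analysis can be exercised and validated without the (large, third-party
hosted) real competition files. Real files in the competition CSV layout
drop in directly.

## What it computes

**Grouped log-MAE score.** Submissions are scored by

```
score = (1/T) Σ_t ln( (1/n_t) Σ_i |y_i − ŷ_i| )
```

with `t` over the T = 8 coupling types and `n_t` the per-type record
count. Because each type enters through the log of its own MAE, no
abundant or large-valued coupling class dominates; `exp(score)` is the
geometric-mean error in Hz, and a score *difference* Δ maps to an
`exp(Δ)`-fold change in accuracy.

**Meta-ensembles (ME).** Stacked predictions `ŷ_ME = Σ_{j=k..N} w_j ŷ_j`
with `w_j ≥ 0, Σ w_j = 1`, fitted by minimizing the score on half of the
test records (type-stratified), evaluated on the other half. The
k-exclusion sweep drops the top k−1 models and refits, quantifying how
much of the leaders' accuracy the rest of the field already contains.
Per-type weights and median combining are supported variants.

**Residual-correlation clustering.** Pearson correlation between
submissions' residual vectors (prediction − truth), ordered by
agglomerative clustering on 1 − r — the dendrogram/heatmap view of which
modelling lineages err alike, and which team is the odd one out.

**Leaderboard dynamics.** Running-best score traces and a separable
multi-start fit of the bi-exponential progress curve
`A·exp(−t/τ₁) + B·exp(−t/τ₂) + C`, separating the fast
baseline-adoption phase from slow long-run refinement.

**Synthetic competitions.** A generator that plants the structure the
analyses assume: unbalanced type abundances with type-specific value
scales, a 65/35 molecule-level train/test split, a 29/71 record-level
public/private split, and teams whose errors are cluster-correlated and
shrink over time along a bi-exponential envelope — all reproducible from
one master seed.

## Worked example

```python
import couplingswarm as cs

cfg = cs.PopulationConfig(n_molecules=600, couplings_per_molecule=20,
                          n_teams=10, n_clusters=3,
                          within_cluster_correlation=0.6,
                          submissions_per_team=4, seed=42)
dataset = cs.generate_dataset(cfg)
submissions = cs.generate_submissions(dataset, cfg)

board = cs.rank_submissions(submissions, dataset, "public")
fit = cs.fit_weights(submissions, dataset, k=1, seed=0)
trace = cs.generate_leaderboard_history(submissions, dataset)
curve = cs.fit_biexponential(trace)
```

Formatting the returned objects prints:

```
12000 records, 600 molecules, 1218 public test records
rank 1: team_001  score -6.502  geo. mean error 0.0015 Hz
rank 2: team_005  score -6.225  geo. mean error 0.0020 Hz
rank 3: team_008  score -6.154  geo. mean error 0.0021 Hz
ME eval score -6.852 (best individual public score -6.502); 9 contributors with w > 0.01
progress curve: tau_fast 3.25 d, tau_slow 33.6 d, asymptote -6.62
```

Reading it: the winning team's geometric-mean error is 0.0015 Hz; the
stacked meta-ensemble of all 40 submissions scores −6.852 on held-out
records, beating every individual (a score gain of 0.35 ≈ 1.4× accuracy),
with 9 submissions carrying weight above 0.01; and the leader trace is
described by a fast ~3-day and a slow ~34-day time constant.

The same pipeline runs from the shell:

```sh
couplingswarm simulate --seed 42 --out sim/          # writes train/test/truth CSVs + submissions
couplingswarm score --truth sim/truth.csv --pred sim/submissions/team_001_s03.csv --split public
couplingswarm sweep --truth sim/truth.csv --pred-dir sim/submissions --k-max 10 --out sweep.csv
couplingswarm cluster --truth sim/truth.csv --pred-dir sim/submissions --out corr.csv --tree tree.txt
couplingswarm run --seed 42 --out run/               # everything, plus summary.json
```

## Layout

- `src/couplingswarm/scoring.py` — the metric, geometric-mean transform, ranking
- `src/couplingswarm/ensemble.py` — simplex-weight fitting, k-sweep, grid-search oracle
- `src/couplingswarm/similarity.py` — residual correlation, clustering, outlier ranking
- `src/couplingswarm/dynamics.py` — running best, bi-exponential fit, phase summary
- `src/couplingswarm/synthetic.py` — the competition generator
- `src/couplingswarm/io.py`, `cli.py` — competition CSV layout and the umbrella CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
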