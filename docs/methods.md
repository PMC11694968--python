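# Methods

This note records the models and procedures implemented in `injurypred`,
the assumptions behind them, the parameter choices that matter, and what
the synthetic data can and cannot show.

## Problem setting

The unit of analysis is the *player-day*: one row per player per calendar
day over a season, with aggregated GPS workload metrics, encoded
descriptive variables, and a binary label (1 = a noncontact injury was
recorded for that player on that day). Injuries are rare (~0.2% of
player-days), so the whole design is organized around class imbalance:
cost-sensitive losses, centroid undersampling, GMEAN-based selection, and
a sensitivity-favoring threshold rule.

## Synthetic season generator

Club workload data are private; the generator (`synthetic.py`) emulates
the cohort a season of first-division football produces. Defaults are the
study conditions: 34 players weighted over five positions (11/9/7/4/3),
a 36-week calendar (2020-09-07..2021-05-19) with 6 training sessions and
~1.06 matches per week (≈217 training days and ≈38 matches), several
hundred metric columns, and an expected 18 injuries.

* **Metrics** are correlated log-normal draws: a per-exercise latent
  factor f ~ N(0,1) mixed with independent noise at weight √ρ (ρ =
  `metric_corr`, default 0.6), exponentiated with per-metric location and
  scale fixed by a schema RNG. This gives the nonnegative, right-skewed,
  mutually correlated shape of real GPS exports, which winsorization and
  mRMR need in order to be exercised meaningfully. A small set of
  rescaled duplicate columns (`dupK_of_*`) is injected deliberately so
  redundancy handling is testable, and two quality columns (`hdop_avg`,
  `sat_count_max`) exist only to be dropped.
* **Calendar structure**: players miss training with probability 0.12 and
  matches with probability 0.42 (squad rotation), and training days hold
  2–5 exercises. A match is generated as a single block whose workload
  (intensity 8× the per-exercise base) exceeds a whole training day
  (~3.5 exercises); this calibration makes the injury context split come
  out at the cohort's reported proportion (~56% of injuries in matches).
* **Hazard model.** The source study is observational and reveals no
  injury-generating mechanism; the hazard here is this package's own
  construct, built to embody the rationale for dummy days (sudden changes
  in the load time series raise risk). For an active day *t* with daily
  load series L:

      p(t) = clip( b · exp(s · z⁺(t)) · exp(r · rest(t)), 0, 1 )

  where z⁺(t) is the positive z-score of L(t) against the previous 14
  days (sample SD; 0 if fewer than 2 prior days or SD = 0), rest(t)
  indicates an active day after ≥2 zero-load days, b =
  `baseline_hazard` (0.002), s = `spike_coef` (0.8), r = `rest_gap_coef`
  (0.7). When `target_injuries` is set (default 18) the baseline is
  rescaled so the hazards sum to the target over the realized schedule,
  which keeps the seasonal injury count near the cohort's. Injuries are
  drawn per active day (never on rest days) and logged with their
  match/training context.
* **Not modelled**: biomechanical realism, 10 Hz traces, heart rate,
  wellness/questionnaire data, injury severity or layoff periods, and any
  within-player susceptibility differences.

Consequence for interpretation: passing end-to-end tests shows the
pipeline recovers a *load-spike* signal planted in data of realistic
shape; it says nothing about effect sizes in real squads.

## Data preparation

Aggregation to player-days uses a per-metric rule: names containing
`max`/`peak` take the day maximum, `avg`/`mean`/`rate` the mean,
everything else (distances, loads, counts, durations) the sum; unmatched
names fall back to sum with a logged warning. An explicit
`AggregationSpec` (YAML) overrides the heuristic. When a day mixes
training and match rows the match identity wins, since result, location
and competition are day-level facts.

Dummy days span the *global* season range for all players (a continuous
time scale), and zero every measured variable — including descriptive
ones such as age, where a nonzero value would be meaningful. This is a
deliberate fidelity choice; its practical effect is that one-hot groups
sum to 0 on dummy rows and 1 elsewhere, which the models can exploit as
an activity indicator.

One-hot encoding keeps every observed level (no reference level dropped);
blank match-only fields on training days yield all-zero indicator groups.
Player identity is a row key only, never a feature.

## Winsorization and standardization

Bounds are fitted on injured rows only: abnormal workloads can *cause*
injuries and must not be treated as noise, yet the clipping is applied to
all records. The number of SDs adapts per metric
(⌊|min|/σ⌋+1 below, ⌊max/σ⌋+1 above the median), so at least one SD of
range is always kept on each side. Conventions the source formulas leave
open, fixed here: σ is the sample SD (n−1) throughout; a metric whose
injured-row σ is 0 is marked no-clip; a negative minimum would place the
"lower" bound above the median, so |min| is used (raw GPS metrics are
nonnegative; the branch is essentially never hit). Standardization is
plain per-column z-scoring fitted after winsorization; zero-SD columns
pass through flagged. Dummy-day zero rows are included when fitting the
standardizer — they are dataset rows.

**Leakage note.** In the default ("faithful") regime, winsor bounds, the
standardizer and the mRMR ranking are fitted on the complete table before
any splitting — reproducing the original protocol, which builds its folds
from the already-preprocessed dataset. This leaks distributional
information from test players into preprocessing. A leakage-free variant
(`pipeline.run_config_leakage_free`) refits everything inside each
training fold, for methodological comparison; it is off by default.

## mRMR

The ranking is greedy: the first feature maximizes relevance; each next
feature maximizes relevance ÷ mean redundancy with the already-selected
set (quotient rule, guarded at 1e−12; ties break lexicographically so
runs are reproducible). With continuous features and a binary label the
F-statistic/|Pearson r| instantiation (FCQ) is the standard choice and is
the default; a mutual-information variant with equal-width binning
(`method="miq"`) is provided for comparison. One behavioral consequence
of the quotient rule worth knowing: an exact duplicate of the top feature
is typically ranked *second* — its relevance equals the original's and
redundancy saturates at 1, which divides but does not disqualify. The
redundancy column of the exported ranking exposes such duplicates.

## Models

Hyperparameters default to the benchmark configuration: SVM — RBF kernel,
squared-L2 regularization (C unstated there; 1.0 here), probabilities by
Platt scaling (sigmoid calibration on internal ≤5-fold scores); FNN — one
hidden layer of 10 tanh units, dropout 0.6 between hidden and output,
sigmoid output, Adam at lr 0.001 for 20 epochs, class-weighted binary
cross-entropy with an L2 penalty (weight 1e−4 here; batch size 32 and
uniform fan-in initialization are this package's choices); AdaBoost — at
most 50 one-level decision stumps, early-stopped when a stump fits
perfectly. The FNN is a compact NumPy implementation so the weighted
loss, dropout schedule and seeding are exactly as specified and
bit-reproducible. Where the source text is self-contradictory on the FNN
loss (weighted squared error vs binary cross-entropy), weighted BCE is
the default and the squared-error variant sits behind `loss="wse"`.

**Class weights** are w_c = N/(2n_c) in cost-sensitive mode, (1, 1) in
traditional mode — computed on the training split *before* undersampling.
The imbalance that cost-sensitive learning is meant to counter is the
split's true one (~0.2–0.5% positive); computing weights on the already
rebalanced sample (28.6% positive) nearly nullifies the mechanism and, in
our experiments, erases the expected sensitivity advantage.

**Undersampling** replaces noninjured training rows with
round(n_injured/0.40) k-means centroids (injured rows kept verbatim).
The benchmark's "ratio 40% and k = 8" cannot both drive the centroid
count for its stated fold sizes; the ratio semantics
(injured:noninjured = 0.40 after resampling) is used, with k retained as
metadata and an `exact_k` flag for the literal alternative.

## Validation and selection

Folds are subject-wise: injured players are shuffled (seeded) and halved;
fold *f* trains on half *f*'s rows and tests on the other half plus all
never-injured players. Each fold's train and test player sets are
disjoint, every training player has an injury, and each injury record
appears once as training and once as test across the fold pair.

The decision threshold minimizes √((1−sens)² + FPR²) over the distinct
training-split scores (plus a predict-nothing supremum); ties resolve to
the lower threshold, favoring sensitivity. The threshold is always
transferred from train to test. Metrics with an empty denominator (a
split with no positives) surface as NaN with an `undefined` flag — never
as silent zeros. The sweep aggregates mean ± SD per (model, mode, p) over
repetitions (each repetition redraws folds *and* model initialization —
whether the original protocol re-randomized folds per repetition is
unstated; both are re-randomized here), and selection is three-step:
per-group argmax of training GMEAN (ties → smaller p), then group winners
ranked by test GMEAN.

Per-run seeds derive from CRC32 of (base seed, coordinate, repetition),
so any single run is re-derivable in isolation; all derived seeds are
< 2³¹. Default repetitions are 25 (500 reproduces the full protocol of
78 000 runs on the 26-point p-grid).

## Problem sizes used in tests and analyses

The shipped analyses and the test suite run the protocol at reduced
scale, chosen as sensible working sizes: the analysis drivers use a
60-metric panel with 5 repetitions (240 runs); the end-to-end
signal-recovery check uses a 24-player, 16-week season with a strong
spike coefficient (4.0), a selection sweep at 5 repetitions over
p ∈ {10, 20, 30}, 20 evaluation repetitions for the selected model, and a
label-permutation null averaged over 5 permutations (a single permuted
label vector of ~30 injuries retains accidental load correlation, so the
null must be averaged to sit at AUC ≈ 0.5); the cost-sensitivity
direction check uses 20 independent 20-player seasons and compares
training-split sensitivity, which is where the directional claim is
sharpest (threshold transfer makes test-split sensitivity much noisier at
these sample sizes).

## Known limitations

* The hazard model is a construct; real injury aetiology is multifactorial
  and not reducible to load spikes and rest gaps.
* The faithful preprocessing regime leaks test-player distributional
  information by design; use the leakage-free variant for honest
  generalization estimates.
* With ~10–30 injuries per season, every test-split metric has large
  variance; single-season results are anecdotes, which is why the sweep
  reports mean ± SD over repetitions.
* AdaBoost reliably memorizes the small rebalanced training split
  (training GMEAN 100%); its training metrics carry no information about
  generalization.
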