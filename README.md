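# injurypred

Daily noncontact-injury risk prediction for professional football squads
from GPS workload data.

Noncontact injuries (acute pain during training or a match, without player
contact, causing absence from the next session) are rare — on the order of
0.2% of player-days over a season — yet costly. This package implements a
complete season-long forecasting pipeline for sports scientists and
performance staff: from raw per-exercise GPS session records to daily,
per-player injury probabilities from cost-sensitive classifiers, validated
player-by-player so no model ever sees the player it is judged on.

Because club workload data are private, the package ships a seeded
synthetic season generator that reproduces the statistical shape of a
first-division squad's year (34 players in five positions, a 36-week
calendar with ~217 training sessions and ~38 matches, hundreds of
correlated right-skewed GPS metrics, ~18 injuries concentrated on
load-spike days). Every stage is therefore fully testable offline.

## The pipeline

1. **Data preparation** — exercise-level rows are aggregated to one record
   per (player, day) (sums for loads/distances/counts, maxima for peak
   metrics, means for rates); GPS-quality columns (HDOP, satellite counts)
   are dropped; days with no activity are inserted as all-zero *dummy
   days* so every player has a continuous time scale; categorical
   descriptors (position, corridor, day of week, session type, match
   result/location/competition) are one-hot encoded.
2. **Preprocessing** — adaptive winsorization with bounds estimated from
   *injured* rows only: for metric *i* with median x̃ᵢ, sample SD σᵢ,
   minimum minᵢ and maximum maxᵢ,

   xᵢᴸ = x̃ᵢ − (⌊|minᵢ|/σᵢ⌋ + 1)·σᵢ,  xᵢᵁ = x̃ᵢ + (⌊maxᵢ/σᵢ⌋ + 1)·σᵢ,

   and every record is clipped into [xᵢᴸ, xᵢᵁ]; columns are then z-scored:
   xᵢ ← (xᵢ − x̄ᵢ)/σᵢ.
3. **Feature selection** — zero-variance columns removed; the rest ranked
   by greedy mRMR (relevance = F-statistic against the injury label,
   redundancy = mean |Pearson r| with already-selected features, quotient
   score); a wrapper sweep then tests the top-p subsets, p = 10, 20, ….
4. **Models** — RBF-kernel SVM with Platt-scaled probabilities, a small
   feedforward net (10 tanh units, dropout 0.6, sigmoid output, Adam,
   20 epochs, class-weighted binary cross-entropy), and AdaBoost over at
   most 50 decision stumps — each in *cost-sensitive* mode (class costs
   inversely proportional to class frequencies, w_c = N/(2n_c)) or
   *traditional* mode (unit costs). Training splits are rebalanced by
   replacing noninjured rows with k-means centroids at an
   injured:noninjured ratio of 0.40.
5. **Evaluation** — two player-disjoint folds splitting the injured
   players 50/50; the decision threshold is the ROC point nearest
   (FPR = 0, sensitivity = 1) ("elbow"), fitted on the training split and
   transferred to the test split; models are compared by
   GMEAN = √(sensitivity × specificity) and selected in three steps
   (best p per model/mode by training GMEAN, then winners ranked by test
   GMEAN).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
season (seed 1, 60-metric panel) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_prepare.py
python analysis/03_rank_features.py
python analysis/04_sweep.py
python analysis/05_select_best.py
```

which prints, stage by stage:

```
season 2020-09-07..2021-05-19: 23490 exercise rows, 219 training days, 36 match days
17 injuries (52.94% in matches, 47.06% in training) -> results/
8670 player-day rows (1429 dummy days), 84 feature columns, 17 injury days -> results/player_days.csv
84 features ranked (0 zero-variance removed); top 5: player_load, avg_accel_band8, ...
240 runs (48 configurations x 5 repetitions, 2 folds each) -> results/sweep.csv
group winners (ranked by test GMEAN):
  fnn      cost-sensitive p= 80  train GMEAN  69.11%  test GMEAN  65.73%  test AUC 0.84
  svm      traditional    p= 80  train GMEAN  85.32%  test GMEAN  61.04%  test AUC 0.70
  adaboost traditional    p= 10  train GMEAN 100.00%  test GMEAN  55.75%  test AUC 0.62
  ...
best model: fnn (cost-sensitive, p=80)
```

Reading: the season produced 8670 player-days (34 players × 255 days) with
17 injury days; after the sweep, the cost-sensitive feedforward net with
the top 80 mRMR features generalizes best — it ranks unseen players'
injury days above their normal days with AUC 0.84, and at its transferred
elbow threshold balances sensitivity and specificity at a geometric mean
of 65.7%. AdaBoost memorizes its small rebalanced training split (training
GMEAN 100%) but transfers worst — exactly the overfitting pattern the
player-disjoint validation is there to expose.

The same stages are available as a CLI (`injurypred simulate | prepare |
rank | sweep | select | report`).

## Layout

```
src/injurypred/    library: synthetic, data_prep, preprocess,
                   feature_select, models, evaluation, experiment,
                   pipeline, cli
analysis/          numbered study drivers (write under results/)
tests/             pytest suite incl. property/oracle tests
docs/methods.md    models, assumptions, parameter choices, limitations
```
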