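"""Player-disjoint folds, ROC-elbow thresholds, and the metric suite.

Validation is subject-wise: each player's rows live on exactly one side of
a fold's train/test divide, so a model can never memorise a player.  The
two folds split the injured players ~50/50; a fold trains on one half's
rows and tests on the other half plus every never-injured player, so each
injury record appears in both folds (once as training, once as test).

The decision threshold is the ROC point nearest the top-left corner
("elbow"), fitted on the training split and transferred to the test split.
Model selection uses GMEAN = sqrt(sensitivity × specificity), which is
zero as soon as either class is ignored — the right criterion when one
class (injury) is three orders of magnitude rarer than the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class FoldSplit:
    """One player-disjoint train/test split."""

    fold: int
    train_players: frozenset
    test_players: frozenset
    train_idx: np.ndarray
    test_idx: np.ndarray


def make_folds(table: pd.DataFrame, seed: int = 0) -> tuple[FoldSplit, FoldSplit]:
    """Two complementary subject-wise folds of the player-day table.

    Injured players are shuffled (seeded) and split in half; fold *f*
    trains on half *f*'s rows and tests on the other half's rows plus all
    rows of never-injured players.  Train and test player sets are disjoint
    within each fold, and every train player has at least one injury.
    """
    injured_players = sorted(table.loc[table["injury"] == 1, "player_id"].unique())
    if len(injured_players) < 2:
        raise ValueError("subject-wise folds need at least 2 injured players")
    all_players = set(table["player_id"].unique())
    never_injured = all_players - set(injured_players)

    rng = np.random.default_rng(seed)
    shuffled = list(injured_players)
    rng.shuffle(shuffled)
    h = math.ceil(len(shuffled) / 2)
    half1, half2 = frozenset(shuffled[:h]), frozenset(shuffled[h:])

    pid = table["player_id"]
    idx = np.arange(len(table))

    def split(train_set: frozenset, test_injured: frozenset, fold: int) -> FoldSplit:
        test_set = frozenset(test_injured | never_injured)
        return FoldSplit(
            fold=fold,
            train_players=train_set,
            test_players=test_set,
            train_idx=idx[pid.isin(train_set).to_numpy()],
            test_idx=idx[pid.isin(test_set).to_numpy()],
        )

    return split(half1, half2, 1), split(half2, half1, 2)


def elbow_threshold(y_true, scores) -> float:
    """Score cut-point whose ROC point is nearest (FPR=0, sensitivity=1).

    Candidates are the distinct score values plus a supremum that predicts
    everything negative; prediction is ``score >= threshold``.  Ties in
    elbow distance resolve to the lower threshold (favouring sensitivity).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValueError("length mismatch")
    n_pos = int(np.sum(y_true == 1))
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("elbow threshold needs both classes present")

    candidates = np.unique(scores)
    candidates = np.append(candidates, np.nextafter(candidates[-1], np.inf))
    # cumulative counts of positives/negatives with score >= t, via sorting
    best_t, best_d = None, np.inf
    for t in candidates:  # ascending → ties keep the lower threshold
        pred = scores >= t
        tp = int(np.sum(pred & (y_true == 1)))
        fp = int(np.sum(pred & (y_true == 0)))
        sens = tp / n_pos
        fpr = fp / n_neg
        d = math.hypot(1.0 - sens, fpr)
        if d < best_d - 1e-15:
            best_t, best_d = float(t), d
    return best_t


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with proportion metrics; empty denominators → NaN."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def undefined(self) -> bool:
        return (self.tp + self.fn == 0) or (self.tn + self.fp == 0)


def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    return ConfusionMetrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def gmean(sensitivity: float, specificity: float) -> float:
    """Geometric mean sqrt(sensitivity × specificity)."""
    for v in (sensitivity, specificity):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"metric {v} outside [0, 1]")
    return math.sqrt(sensitivity * specificity)


def auc(y_true, scores) -> float:
    """Rank-based AUC (ties averaged)."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))


@dataclass(frozen=True)
class EvalMetrics:
    """One model's performance on one split at one threshold."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    gmean: float
    threshold: float
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "gmean": self.gmean,
            "threshold": self.threshold,
            "undefined": self.undefined,
        }


def evaluate_scores(y_true, scores, threshold: float) -> EvalMetrics:
    """Apply a (train-fitted) threshold and compute the full metric suite."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    cm = confusion_metrics(y_true, (scores >= threshold).astype(int))
    sens, spec = cm.sensitivity, cm.specificity
    both = len(np.unique(y_true)) == 2
    return EvalMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=cm.accuracy,
        auc=auc(y_true, scores) if both else float("nan"),
        gmean=gmean(sens, spec) if not cm.undefined else float("nan"),
        threshold=float(threshold),
        undefined=cm.undefined,
    )
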