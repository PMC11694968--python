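"""Sweep harness: model × learning mode × top-p grid × repetitions.

Each run draws a fresh player-disjoint fold pair, undersamples the
training split with k-means centroids, trains, fits the ROC-elbow
threshold on the training scores and evaluates both splits.  Runs
aggregate to mean ± SD per grid coordinate, and the best models are picked
in three steps: per (model, learning) group the p maximizing the mean
training GMEAN, then those group winners ranked by mean test GMEAN.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import evaluation, feature_select, models
from .evaluation import EvalMetrics
from .feature_select import FeatureRanking
from .models import ModelSpec, UndersampleConfig
from .synthetic import InjuryLog

MODEL_KINDS = ("svm", "fnn", "adaboost")
LEARNING_MODES = (True, False)  # cost-sensitive, traditional

METRIC_FIELDS = ("sensitivity", "specificity", "accuracy", "auc", "gmean")


def derive_seed(base_seed: int, *parts) -> int:
    """Stable per-run seed < 2**31 from a base seed and coordinates."""
    key = repr((base_seed,) + parts).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass(frozen=True)
class SweepGrid:
    """The experiment grid; the full protocol is 3 × 2 × 26 × 500 = 78 000."""

    models: Sequence[str] = MODEL_KINDS
    modes: Sequence[bool] = LEARNING_MODES
    p_grid: Sequence[int] = tuple(range(10, 261, 10))
    repetitions: int = 25
    base_seed: int = 0

    @property
    def n_configurations(self) -> int:
        return len(self.models) * len(self.modes) * len(self.p_grid)

    @property
    def total_runs(self) -> int:
        return self.n_configurations * self.repetitions

    def iter_coordinates(self):
        return itertools.product(self.models, self.modes, self.p_grid)

    def iter_runs(self):
        return itertools.product(
            self.models, self.modes, self.p_grid, range(self.repetitions)
        )


@dataclass(frozen=True)
class RunRecord:
    """Metrics for one (coordinate, fold, repetition)."""

    model: str
    cost_sensitive: bool
    p: int
    fold: int
    repetition: int
    seed: int
    train: EvalMetrics
    test: EvalMetrics

    def as_row(self) -> dict:
        row = {
            "model": self.model,
            "cost_sensitive": self.cost_sensitive,
            "p": self.p,
            "fold": self.fold,
            "repetition": self.repetition,
            "seed": self.seed,
        }
        for split, m in (("train", self.train), ("test", self.test)):
            for f in METRIC_FIELDS + ("threshold",):
                row[f"{split}_{f}"] = getattr(m, f)
        return row


def _fit_eval_fold(
    table: pd.DataFrame,
    features: list[str],
    fold: evaluation.FoldSplit,
    kind: str,
    cost_sensitive: bool,
    seed: int,
    undersample: UndersampleConfig | None,
) -> tuple[EvalMetrics, EvalMetrics]:
    X = table[features]
    y = table["injury"].to_numpy(dtype=int)
    X_tr, y_tr = X.iloc[fold.train_idx], y[fold.train_idx]
    X_te, y_te = X.iloc[fold.test_idx], y[fold.test_idx]

    # class costs reflect the split's true imbalance, before rebalancing
    weights = models.compute_class_weights(y_tr, cost_sensitive)

    if undersample is not None:
        cfg = UndersampleConfig(
            ratio=undersample.ratio,
            k=undersample.k,
            exact_k=undersample.exact_k,
            seed=seed,
        )
        X_tr, y_tr = models.kmeans_undersample(
            X_tr.reset_index(drop=True), y_tr, cfg
        )

    spec = ModelSpec(kind=kind, cost_sensitive=cost_sensitive, seed=seed)
    clf = models.train(spec, X_tr, y_tr, weights)

    s_tr = clf.predict_proba(X_tr)
    thr = evaluation.elbow_threshold(y_tr, s_tr)
    m_tr = evaluation.evaluate_scores(y_tr, s_tr, thr)
    s_te = clf.predict_proba(X_te)
    m_te = evaluation.evaluate_scores(y_te, s_te, thr)
    return m_tr, m_te


def run_config(
    table: pd.DataFrame,
    ranking: FeatureRanking,
    kind: str,
    cost_sensitive: bool,
    p: int,
    repetitions: int,
    base_seed: int = 0,
    undersample: UndersampleConfig | None = UndersampleConfig(),
) -> list[RunRecord]:
    """All repetitions of one grid coordinate (both folds each)."""
    features = feature_select.top_p(ranking, p)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"ranked features absent from table: {missing[:5]}")
    records = []
    for rep in range(repetitions):
        seed = derive_seed(base_seed, kind, cost_sensitive, p, rep)
        folds = evaluation.make_folds(table, seed=seed)
        for fold in folds:
            m_tr, m_te = _fit_eval_fold(
                table, features, fold, kind, cost_sensitive, seed, undersample
            )
            records.append(
                RunRecord(
                    model=kind,
                    cost_sensitive=cost_sensitive,
                    p=p,
                    fold=fold.fold,
                    repetition=rep,
                    seed=seed,
                    train=m_tr,
                    test=m_te,
                )
            )
    return records


def records_to_frame(records: Iterable[RunRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def aggregate_records(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of every metric per (model, learning, p) coordinate."""
    cols = [
        f"{split}_{f}" for split in ("train", "test") for f in METRIC_FIELDS
    ]
    g = raw.groupby(["model", "cost_sensitive", "p"])
    agg = g[cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    agg["n_runs"] = g.size()
    return agg.reset_index()


def run_sweep(
    table: pd.DataFrame,
    ranking: FeatureRanking,
    grid: SweepGrid,
    undersample: UndersampleConfig | None = UndersampleConfig(),
    keep_records: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Execute the whole grid; returns (aggregated table, raw records)."""
    if grid.n_configurations == 0 or grid.repetitions == 0:
        raise ValueError("empty sweep grid")
    all_records: list[RunRecord] = []
    for kind, mode, p in grid.iter_coordinates():
        all_records.extend(
            run_config(
                table,
                ranking,
                kind,
                mode,
                p,
                grid.repetitions,
                base_seed=grid.base_seed,
                undersample=undersample,
            )
        )
    raw = records_to_frame(all_records)
    expected = grid.total_runs * 2  # two folds per run
    assert len(raw) == expected, (len(raw), expected)
    agg = aggregate_records(raw)
    return agg, (raw if keep_records else None)


@dataclass
class BestModelReport:
    """Per-group winners (chosen p + metrics) and the overall ranking."""

    groups: list[dict] = field(default_factory=list)  # ordered by test GMEAN
    overall: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"groups": self.groups, "overall": self.overall}, fh, indent=1)


def select_best(agg: pd.DataFrame) -> BestModelReport:
    """Three-step selection on the aggregated sweep table.

    Within each (model, learning) group, pick the p with the highest mean
    training GMEAN (ties → smaller p); then rank the group winners by mean
    test GMEAN.
    """
    if agg.empty:
        raise ValueError("empty sweep table")
    report = BestModelReport()
    winners = []
    for (model, cs), g in agg.groupby(["model", "cost_sensitive"]):
        g = g.sort_values(["train_gmean_mean", "p"], ascending=[False, True])
        best = g.iloc[0]
        winners.append(
            {
                "model": model,
                "cost_sensitive": bool(cs),
                "p": int(best["p"]),
                "train_gmean": float(best["train_gmean_mean"]),
                "test_gmean": float(best["test_gmean_mean"]),
                "train_sensitivity": float(best["train_sensitivity_mean"]),
                "test_sensitivity": float(best["test_sensitivity_mean"]),
                "test_specificity": float(best["test_specificity_mean"]),
                "test_auc": float(best["test_auc_mean"]),
            }
        )
    winners.sort(key=lambda w: -w["test_gmean"])
    report.groups = winners
    report.overall = winners[0] if winners else None
    return report


def injury_context_summary(log: InjuryLog | pd.DataFrame) -> dict:
    """Injury counts by context with the match-related percentage.

    With the study's printed counts (18 injuries, 10 in matches) this
    reports 55.56% match-related.
    """
    df = log.to_frame() if isinstance(log, InjuryLog) else log
    n = len(df)
    n_match = int((df["context"] == "match").sum()) if n else 0
    n_training = n - n_match
    return {
        "n_injuries": n,
        "n_match": n_match,
        "n_training": n_training,
        "pct_match": round(100.0 * n_match / n, 2) if n else float("nan"),
        "pct_training": round(100.0 * n_training / n, 2) if n else float("nan"),
    }


def permute_labels(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Null control: shuffle the injury column across player-days."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    y = out["injury"].to_numpy().copy()
    rng.shuffle(y)
    out["injury"] = y
    return out
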