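"""End-to-end wiring: preparation → preprocessing → ranking → sweep.

Two preprocessing regimes are offered:

* **faithful** (default): winsor bounds, the standardizer and the mRMR
  ranking are fitted on the COMPLETE player-day table before any
  splitting, mirroring the original protocol (splits are created from the
  already-preprocessed dataset).  This leaks distributional information
  from test players into preprocessing — deliberately kept, as it is the
  protocol being reproduced.
* **leakage-free**: bounds/standardizer/ranking are refitted inside each
  training split and applied to its test split, for methodological
  comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import data_prep, evaluation, feature_select, models, preprocess
from .experiment import RunRecord, derive_seed
from .feature_select import FeatureRanking
from .models import ModelSpec, UndersampleConfig


@dataclass
class PreparedDataset:
    """Preprocessed player-day table with its fitted transforms and ranking."""

    table: pd.DataFrame
    features: list[str]
    bounds: preprocess.WinsorBounds
    standardizer: preprocess.Standardizer
    ranking: FeatureRanking
    removed_zero_variance: list[str]


def preprocess_and_rank(
    table: pd.DataFrame, mrmr_method: str = "fcq"
) -> PreparedDataset:
    """Faithful whole-dataset preprocessing + mRMR ranking.

    Winsorization applies to the GPS metric columns (bounds from injured
    rows); standardization to every numeric feature column; zero-variance
    columns are then removed and the rest ranked.
    """
    metric_cols = [
        c
        for c in data_prep.metric_columns(table)
        if pd.api.types.is_numeric_dtype(table[c])
    ]
    injured = table[table["injury"] == 1]
    bounds = preprocess.fit_winsor_bounds(injured, columns=metric_cols)
    tw = preprocess.winsorize(table, bounds)

    feat_cols = data_prep.feature_columns(tw)
    standardizer = preprocess.fit_standardizer(tw, columns=feat_cols)
    ts = preprocess.standardize(tw, standardizer)

    ts, removed = feature_select.drop_zero_variance(ts, columns=feat_cols)
    kept = [c for c in feat_cols if c not in removed]
    ranking = feature_select.mrmr_rank(
        ts[kept], ts["injury"].to_numpy(), method=mrmr_method
    )
    return PreparedDataset(
        table=ts,
        features=kept,
        bounds=bounds,
        standardizer=standardizer,
        ranking=ranking,
        removed_zero_variance=removed,
    )


def run_config_leakage_free(
    raw_table: pd.DataFrame,
    kind: str,
    cost_sensitive: bool,
    p: int,
    repetitions: int,
    base_seed: int = 0,
    undersample: UndersampleConfig | None = UndersampleConfig(),
    mrmr_method: str = "fcq",
) -> list[RunRecord]:
    """Leakage-free variant: transforms and ranking refitted per fold.

    ``raw_table`` is the encoded player-day table BEFORE winsorization /
    standardization.  Folds with fewer than two injured training rows skip
    winsorization (bounds undefined) and are otherwise processed normally.
    """
    records = []
    metric_cols = [
        c
        for c in data_prep.metric_columns(raw_table)
        if pd.api.types.is_numeric_dtype(raw_table[c])
    ]
    for rep in range(repetitions):
        seed = derive_seed(base_seed, "lf", kind, cost_sensitive, p, rep)
        folds = evaluation.make_folds(raw_table, seed=seed)
        for fold in folds:
            tr = raw_table.iloc[fold.train_idx].reset_index(drop=True)
            te = raw_table.iloc[fold.test_idx].reset_index(drop=True)
            injured_tr = tr[tr["injury"] == 1]
            if len(injured_tr) >= 2:
                bounds = preprocess.fit_winsor_bounds(injured_tr, columns=metric_cols)
                tr = preprocess.winsorize(tr, bounds)
                te = preprocess.winsorize(te, bounds)
            feat_cols = data_prep.feature_columns(tr)
            std = preprocess.fit_standardizer(tr, columns=feat_cols)
            tr = preprocess.standardize(tr, std)
            te = preprocess.standardize(te, std)
            tr_nz, removed = feature_select.drop_zero_variance(tr, columns=feat_cols)
            kept = [c for c in feat_cols if c not in removed]
            ranking = feature_select.mrmr_rank(
                tr_nz[kept], tr_nz["injury"].to_numpy(), method=mrmr_method
            )
            feats = feature_select.top_p(ranking, min(p, len(ranking)))

            X_tr, y_tr = tr[feats], tr["injury"].to_numpy(dtype=int)
            X_te, y_te = te[feats], te["injury"].to_numpy(dtype=int)
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
            records.append(
                RunRecord(
                    model=kind,
                    cost_sensitive=cost_sensitive,
                    p=p,
                    fold=fold.fold,
                    repetition=rep,
                    seed=seed,
                    train=evaluation.evaluate_scores(y_tr, s_tr, thr),
                    test=evaluation.evaluate_scores(
                        y_te, clf.predict_proba(X_te), thr
                    ),
                )
            )
    return records
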