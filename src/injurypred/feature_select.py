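"""Zero-variance filtering and greedy mRMR feature ranking.

mRMR (maximum relevance, minimum redundancy) orders features so that each
one added is highly informative about the injury label while overlapping
little with those already chosen.  The default scheme here is the F-test
correlation-quotient (FCQ) variant, the standard choice for continuous
features against a binary label: relevance is the one-way ANOVA
F-statistic of the feature versus the label, redundancy the mean absolute
Pearson correlation with the already-selected set, and the greedy score
their quotient.  A mutual-information variant with equal-width binning is
available for comparison via ``method="miq"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

_EPS = 1e-12


@dataclass
class FeatureRanking:
    """Greedy mRMR selection order with per-step scores."""

    names: list[str] = field(default_factory=list)
    relevance: list[float] = field(default_factory=list)
    redundancy: list[float] = field(default_factory=list)
    score: list[float] = field(default_factory=list)
    method: str = "fcq"

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.names) + 1),
                "feature": self.names,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
                "score": self.score,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, method: str = "fcq") -> "FeatureRanking":
        df = pd.read_csv(path)
        return cls(
            names=list(df["feature"].astype(str)),
            relevance=list(df["relevance"]),
            redundancy=list(df["redundancy"]),
            score=list(df["score"]),
            method=method,
        )


def drop_zero_variance(table: pd.DataFrame, columns: list[str] | None = None):
    """Remove exactly the constant columns; returns (table, removed names)."""
    if columns is None:
        columns = [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
    removed = [c for c in columns if table[c].nunique(dropna=False) <= 1]
    if columns and len(removed) == len(columns):
        raise ValueError("all candidate columns are constant")
    return table.drop(columns=removed), removed


def _binned_mi(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Mutual information (nats) between equal-width-binned x and discrete y."""
    edges = np.linspace(x.min(), x.max(), bins + 1)
    xb = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    mi = 0.0
    n = len(x)
    for yv in np.unique(y):
        my = y == yv
        py = my.mean()
        for b in range(bins):
            pxy = np.logical_and(my, xb == b).mean()
            px = (xb == b).mean()
            if pxy > 0:
                mi += pxy * np.log(pxy / (px * py))
    return mi


def _relevance(X: pd.DataFrame, y: np.ndarray, method: str) -> np.ndarray:
    if method == "fcq":
        F, _ = f_classif(X.to_numpy(dtype=float), y)
        return np.nan_to_num(F, nan=0.0)
    if method == "miq":
        return np.array(
            [_binned_mi(X[c].to_numpy(dtype=float), y) for c in X.columns]
        )
    raise ValueError(f"unknown mRMR method {method!r}")


def mrmr_rank(
    X: pd.DataFrame,
    y,
    n_rank: int | None = None,
    method: str = "fcq",
) -> FeatureRanking:
    """Greedy mRMR ranking of the columns of ``X`` against binary ``y``.

    The first feature maximizes relevance alone; each subsequent pick
    maximizes relevance / mean|corr| with the already-selected features
    (quotient rule, division guarded at 1e-12).  Ties break
    lexicographically by feature name, so the order is deterministic.
    Zero-variance columns must have been removed beforehand.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("mRMR needs both classes present in y")
    cols = list(X.columns)
    if n_rank is None:
        n_rank = len(cols)
    n_rank = min(n_rank, len(cols))

    rel = dict(zip(cols, _relevance(X, y, method)))
    Xv = X.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(cols)}
    sd = Xv.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [c for c in cols if sd[col_idx[c]] == 0]
        raise ValueError(f"zero-variance columns present: {bad}")
    Z = (Xv - Xv.mean(axis=0)) / sd  # corr(a,b) = mean(z_a * z_b)

    ranking = FeatureRanking(method=method)
    remaining = sorted(cols)
    abs_corr_sum = np.zeros(len(cols))

    for step in range(n_rank):
        if step == 0:
            best = max(remaining, key=lambda c: (rel[c], ))
            # lexicographic tie-break: remaining is sorted, max keeps first
            red_best, score_best = 0.0, rel[best]
        else:
            best, red_best, score_best = None, None, -np.inf
            for c in remaining:
                red = abs_corr_sum[col_idx[c]] / step
                sc = rel[c] / max(red, _EPS)
                if sc > score_best:
                    best, red_best, score_best = c, red, sc
        ranking.names.append(best)
        ranking.relevance.append(float(rel[best]))
        ranking.redundancy.append(float(red_best))
        ranking.score.append(float(score_best))
        remaining.remove(best)
        if remaining:
            zb = Z[:, col_idx[best]]
            corr = np.abs(Z.T @ zb) / len(zb)
            abs_corr_sum += corr
    return ranking


def top_p(ranking: FeatureRanking, p: int) -> list[str]:
    """First ``p`` feature names in mRMR order (nested across p)."""
    if p <= 0:
        raise ValueError("p must be positive")
    if p > len(ranking):
        raise ValueError(f"p={p} exceeds ranked length {len(ranking)}")
    return list(ranking.names[:p])


def p_grid(n_features: int, step: int = 10) -> list[int]:
    """The wrapper-sweep grid 10, 20, ... up to the feature count."""
    return list(range(step, n_features + 1, step))
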