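"""Adaptive winsorization and z-score standardization.

Outlier bounds are estimated from injured players' records only: injuries
can be caused by abnormal workloads, so those extremes must not be treated
as noise.  For metric *i* with median ``x~``, sample SD ``s``, minimum
``mn`` and maximum ``mx`` over the injured rows,

    lower = x~ - (floor(|mn| / s) + 1) * s
    upper = x~ + (floor(mx  / s) + 1) * s

i.e. the number of SDs adapts to each metric's range while always keeping
at least one SD on each side of the median.  Clipping into [lower, upper]
is then applied to every record, injured or not.  Standardization is the
usual per-column (x - mean) / SD, fitted after winsorization.

Note the ``|mn|``: with a negative minimum the textbook expression would
put the "lower" bound above the median, so the magnitude is used instead.
Raw GPS metrics are nonnegative, so this branch is essentially never hit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WinsorBounds:
    """Per-metric clipping bounds fitted on injured rows.

    ``no_clip`` marks metrics whose injured-row SD is zero (degenerate, no
    bounds applicable).
    """

    median: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    min_: dict[str, float] = field(default_factory=dict)
    max_: dict[str, float] = field(default_factory=dict)
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    no_clip: set[str] = field(default_factory=set)

    @property
    def columns(self) -> list[str]:
        return list(self.median)

    def to_json(self, path) -> None:
        d = {
            "median": self.median,
            "sd": self.sd,
            "min": self.min_,
            "max": self.max_,
            "lower": self.lower,
            "upper": self.upper,
            "no_clip": sorted(self.no_clip),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WinsorBounds":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            median=d["median"],
            sd=d["sd"],
            min_=d["min"],
            max_=d["max"],
            lower=d["lower"],
            upper=d["upper"],
            no_clip=set(d["no_clip"]),
        )


def fit_winsor_bounds(
    injured_rows: pd.DataFrame, columns: list[str] | None = None
) -> WinsorBounds:
    """Fit clipping bounds on the injured subset of the player-day table.

    ``injured_rows`` must already be restricted to ``injury == 1`` rows;
    at least two are required for a sample SD to exist.
    """
    if len(injured_rows) == 0:
        raise ValueError("winsor bounds undefined with zero injured rows")
    if len(injured_rows) < 2:
        raise ValueError("winsor bounds need at least 2 injured rows")
    if columns is None:
        columns = [
            c
            for c in injured_rows.columns
            if pd.api.types.is_numeric_dtype(injured_rows[c])
        ]
    b = WinsorBounds()
    for c in columns:
        x = injured_rows[c].to_numpy(dtype=float)
        med = float(np.median(x))
        sd = float(np.std(x, ddof=1))
        mn, mx = float(np.min(x)), float(np.max(x))
        b.median[c], b.sd[c] = med, sd
        b.min_[c], b.max_[c] = mn, mx
        if sd == 0 or not math.isfinite(sd):
            b.no_clip.add(c)
            b.lower[c], b.upper[c] = med, med
            continue
        b.lower[c] = med - (math.floor(abs(mn) / sd) + 1) * sd
        b.upper[c] = med + (math.floor(mx / sd) + 1) * sd
    return b


def winsorize(table: pd.DataFrame, bounds: WinsorBounds) -> pd.DataFrame:
    """Clip every record of each bounded metric into [lower, upper]."""
    missing = [c for c in bounds.columns if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks bounded columns: {missing}")
    out = table.copy()
    for c in bounds.columns:
        if c in bounds.no_clip:
            continue
        out[c] = out[c].clip(lower=bounds.lower[c], upper=bounds.upper[c])
    return out


@dataclass
class Standardizer:
    """Per-column mean/SD transform; zero-SD columns pass through, flagged."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    constant: set[str] = field(default_factory=set)

    @property
    def columns(self) -> list[str]:
        return list(self.mean)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"mean": self.mean, "sd": self.sd, "constant": sorted(self.constant)},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "Standardizer":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean=d["mean"], sd=d["sd"], constant=set(d["constant"]))


def fit_standardizer(
    table: pd.DataFrame, columns: list[str] | None = None
) -> Standardizer:
    """Fit per-column mean and sample SD (ddof=1) on the full table."""
    if len(table) == 0:
        raise ValueError("cannot fit standardizer on an empty table")
    if columns is None:
        columns = [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
    s = Standardizer()
    for c in columns:
        x = table[c].to_numpy(dtype=float)
        m = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        s.mean[c], s.sd[c] = m, sd
        if sd == 0 or not math.isfinite(sd):
            s.constant.add(c)
    return s


def standardize(table: pd.DataFrame, s: Standardizer) -> pd.DataFrame:
    """Apply (x - mean) / sd columnwise; flagged constant columns unchanged."""
    missing = [c for c in s.columns if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks standardized columns: {missing}")
    out = table.copy()
    for c in s.columns:
        if c in s.constant:
            continue
        out[c] = (out[c].astype(float) - s.mean[c]) / s.sd[c]
    return out
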