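"""From exercise-level session records to the player-day feature table.

The modelling unit is one row per player per calendar day.  Raw records
(one row per exercise) are aggregated per (player, date), GPS-quality and
all-missing columns are dropped, idle calendar days are inserted as all-zero
"dummy" rows so every player has a continuous time scale, and categorical
descriptive variables are one-hot encoded.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .synthetic import DESCRIPTIVE_COLS, InjuryLog

logger = logging.getLogger(__name__)

KEY_COLS = ("player_id", "date")
#: descriptive columns carried through aggregation at day level
DAY_DESCRIPTIVE = (
    "session_type",
    "position",
    "corridor",
    "age_months",
    "day_of_week",
    "match_result",
    "match_location",
    "match_competition",
)
DEFAULT_CATEGORICALS = (
    "session_type",
    "position",
    "corridor",
    "day_of_week",
    "match_result",
    "match_location",
    "match_competition",
)
DEFAULT_DROP_PATTERNS = ("hdop", "satellite", "sat_count")

_MAX_PAT = re.compile(r"(^|_)(max|peak)(_|$)")
_MEAN_PAT = re.compile(r"(^|_)(avg|mean|rate|hdop)(_|$)")


@dataclass
class AggregationSpec:
    """Metric-name → aggregation-function mapping with a default rule.

    Unmapped metrics fall back to a suffix heuristic: names containing
    ``max``/``peak`` take the day maximum, ``avg``/``mean``/``rate`` the
    mean, and everything else (distances, loads, counts, durations) the
    day sum.
    """

    rules: dict[str, str] = field(default_factory=dict)
    default: str = "infer"

    VALID = ("sum", "mean", "max")

    def rule_for(self, metric: str) -> str:
        if metric in self.rules:
            return self.rules[metric]
        if self.default != "infer":
            return self.default
        if _MAX_PAT.search(metric):
            return "max"
        if _MEAN_PAT.search(metric):
            return "mean"
        logger.debug("metric %r unmatched by heuristic; aggregating by sum", metric)
        return "sum"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"rules": self.rules, "default": self.default}, fh)

    @classmethod
    def from_yaml(cls, path) -> "AggregationSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(rules=dict(d.get("rules", {})), default=d.get("default", "infer"))


def metric_columns(table: pd.DataFrame) -> list[str]:
    """Columns that are GPS metrics (not keys, descriptives or labels)."""
    known = set(DESCRIPTIVE_COLS) | {"n_exercises", "is_dummy", "injury"}
    return [c for c in table.columns if c not in known]


def aggregate_sessions(
    records: pd.DataFrame, spec: AggregationSpec | None = None
) -> pd.DataFrame:
    """Collapse exercise rows into one record per (player, date).

    Each metric is combined by its :class:`AggregationSpec` rule; the number
    of exercises in the day is added as ``n_exercises``.  If a day mixes
    training and match rows, the match identity (and its result/location/
    competition descriptors) wins, since a matchday is a day-level fact.
    """
    spec = spec or AggregationSpec()
    if records.empty:
        cols = list(KEY_COLS) + list(DAY_DESCRIPTIVE) + ["n_exercises"]
        return pd.DataFrame(columns=cols)
    metrics = [c for c in metric_columns(records) if c != "exercise_idx"]

    agg_map = {m: spec.rule_for(m) for m in metrics}
    grouped = records.groupby(list(KEY_COLS), sort=True)
    out = grouped.agg(agg_map) if metrics else grouped.size().to_frame()[[]]

    desc_rows = []
    for (pid, date), g in grouped:
        is_match = (g["session_type"] == "match").any()
        if is_match and (g["session_type"] != "match").any():
            logger.info("player %s %s: mixed session types, match wins", pid, date)
        src = g[g["session_type"] == "match"].iloc[0] if is_match else g.iloc[0]
        desc_rows.append(
            {
                "player_id": pid,
                "date": date,
                "session_type": "match" if is_match else "training",
                "position": src["position"],
                "corridor": src["corridor"],
                "age_months": src["age_months"],
                "day_of_week": src["day_of_week"],
                "match_result": src["match_result"] if is_match else "",
                "match_location": src["match_location"] if is_match else "",
                "match_competition": src["match_competition"] if is_match else "",
                "n_exercises": len(g),
            }
        )
    desc = pd.DataFrame(desc_rows).set_index(list(KEY_COLS))
    table = desc.join(out).reset_index()
    return table


def attach_injuries(table: pd.DataFrame, log: InjuryLog) -> pd.DataFrame:
    """Add the binary ``injury`` label from the medical log."""
    table = table.copy()
    injured = {(p, d) for p, d, _ in log.entries}
    table["injury"] = [
        int((p, d) in injured) for p, d in zip(table["player_id"], table["date"])
    ]
    return table


def drop_invalid_metrics(
    table: pd.DataFrame, drop_patterns: Iterable[str] = DEFAULT_DROP_PATTERNS
) -> pd.DataFrame:
    """Remove GPS-quality columns and entirely missing metric columns.

    ``drop_patterns`` are case-insensitive substrings matched against metric
    names (satellite counts, HDOP).  Columns that are all-missing are also
    removed, mirroring the removal of sensor channels that never reported.
    """
    patterns = [p.lower() for p in drop_patterns]
    if not patterns:
        raise ValueError("drop_patterns must be nonempty")
    metrics = metric_columns(table)
    to_drop = [m for m in metrics if any(p in m.lower() for p in patterns)]
    to_drop += [m for m in metrics if m not in to_drop and table[m].isna().all()]
    if set(to_drop) >= set(metrics):
        raise ValueError("all metric columns would be dropped")
    if to_drop:
        logger.info(
            "dropping %d invalid metric columns (%d kept)",
            len(to_drop),
            len(metrics) - len(to_drop),
        )
    return table.drop(columns=to_drop)


def insert_dummy_days(
    table: pd.DataFrame, calendar_start: dt.date, calendar_end: dt.date
) -> pd.DataFrame:
    """Give every player exactly one row per calendar day.

    Days without physical activity become dummy rows: a series of zeroes
    across all measured variables (categoricals blank), ``is_dummy = 1``,
    ``injury = 0``.  Existing rows are untouched apart from gaining
    ``is_dummy = 0``.
    """
    if calendar_start > calendar_end:
        raise ValueError("calendar_start must not exceed calendar_end")
    table = table.copy()
    if "is_dummy" not in table.columns:
        table["is_dummy"] = 0
    days = [d.date() for d in pd.date_range(calendar_start, calendar_end, freq="D")]
    players = sorted(table["player_id"].unique())
    have = set(zip(table["player_id"], table["date"]))

    numeric = [
        c
        for c in table.columns
        if c not in KEY_COLS and pd.api.types.is_numeric_dtype(table[c])
    ]
    non_numeric = [
        c for c in table.columns if c not in KEY_COLS and c not in numeric
    ]
    new_rows = []
    for pid in players:
        for day in days:
            if (pid, day) not in have:
                row = {c: 0 for c in numeric}
                row.update({c: "" for c in non_numeric})
                row.update({"player_id": pid, "date": day, "is_dummy": 1})
                if "injury" in table.columns:
                    row["injury"] = 0
                new_rows.append(row)
    out = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
    out = out.sort_values(list(KEY_COLS), kind="stable").reset_index(drop=True)
    # restrict to the requested calendar
    mask = [(calendar_start <= d <= calendar_end) for d in out["date"]]
    return out[mask].reset_index(drop=True)


def encode_descriptive(
    table: pd.DataFrame,
    categorical_fields: Iterable[str] = DEFAULT_CATEGORICALS,
    known_levels: Mapping[str, list] | None = None,
) -> pd.DataFrame:
    """One-hot encode categorical descriptive variables (no level dropped).

    Each field becomes one 0/1 indicator column per observed level, named
    ``field=level``.  Blank / missing values (dummy rows, match-only fields
    on training days) yield all-zero indicator groups.  ``known_levels``
    fixes the level set per field; levels listed there but unobserved still
    get (all-zero) columns, and observed levels missing from it trigger a
    warning and are encoded anyway.
    """
    table = table.copy()
    fields = [f for f in categorical_fields if f in table.columns]
    for fld in fields:
        col = table[fld].astype(object)
        col = col.where(~col.isin(["", None]), other=np.nan)
        observed = sorted({v for v in col.dropna().unique()})
        levels = list(known_levels.get(fld, observed)) if known_levels else observed
        extra = [v for v in observed if v not in levels]
        if extra:
            logger.warning("field %r: unseen levels %s encoded anyway", fld, extra)
            levels = levels + extra
        for lev in levels:
            table[f"{fld}={lev}"] = (col == lev).astype(int)
        table = table.drop(columns=[fld])
    return table


def write_player_day_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_player_day_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["date"] = df["date"].map(lambda s: dt.date.fromisoformat(str(s)))
    for c in ("is_dummy", "injury"):
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df


def build_player_day_table(
    sessions: pd.DataFrame,
    log: InjuryLog,
    calendar_start: dt.date,
    calendar_end: dt.date,
    spec: AggregationSpec | None = None,
    drop_patterns: Iterable[str] = DEFAULT_DROP_PATTERNS,
    categorical_fields: Iterable[str] = DEFAULT_CATEGORICALS,
) -> pd.DataFrame:
    """Full preparation chain: aggregate → drop → label → dummy days → encode."""
    table = aggregate_sessions(sessions, spec)
    table = drop_invalid_metrics(table, drop_patterns)
    table = attach_injuries(table, log)
    table = insert_dummy_days(table, calendar_start, calendar_end)
    table = encode_descriptive(table, categorical_fields)
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric model-input columns (excludes keys, flags and the label)."""
    skip = {"player_id", "date", "is_dummy", "injury"}
    return [
        c
        for c in table.columns
        if c not in skip and pd.api.types.is_numeric_dtype(table[c])
    ]
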