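"""Seeded synthetic football seasons with GPS-like workload structure.

Real club workload data are private, so every downstream stage of the
pipeline is exercised on simulated seasons that reproduce the statistical
shape of a professional squad's year: ~34 players across five positions,
a ~36-week calendar with roughly six training sessions and one match per
week, several hundred correlated, nonnegative, right-skewed GPS metrics,
and a handful of noncontact injuries concentrated on days where a player's
load spikes above their recent norm (especially after a rest gap).

The injury-generating hazard is a modelling construct of this package —
observational studies do not reveal one — and is documented in the methods
note.  Injuries only ever occur on session days.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

POSITIONS = (
    "defender",
    "attacking-midfielder",
    "forward",
    "defensive-midfielder",
    "midfielder",
)

#: squad composition of a first-division cohort: 11/9/7/4/3 of 34
DEFAULT_POSITION_WEIGHTS: Mapping[str, float] = {
    "defender": 11 / 34,
    "attacking-midfielder": 9 / 34,
    "forward": 7 / 34,
    "defensive-midfielder": 4 / 34,
    "midfielder": 3 / 34,
}

CORRIDORS = ("left", "central", "right")
MATCH_RESULTS = ("win", "draw", "loss")
MATCH_LOCATIONS = ("home", "away")
COMPETITIONS = ("league", "cup")

#: descriptive (non-metric) columns of the session table, in output order
DESCRIPTIVE_COLS = (
    "player_id",
    "date",
    "session_type",
    "exercise_idx",
    "position",
    "corridor",
    "age_months",
    "day_of_week",
    "match_result",
    "match_location",
    "match_competition",
)


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Season-generator settings.

    Defaults emulate the study cohort: 34 players over a 36-week season
    (2020-09-07 .. 2021-05-19) with ~217 training sessions, ~38 matches and
    an expected 18 injuries (~0.2% of player-days).
    """

    n_players: int = 34
    position_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_WEIGHTS)
    )
    season_start: dt.date = dt.date(2020, 9, 7)
    season_end: dt.date = dt.date(2021, 5, 19)
    sessions_per_week: int = 6
    matches_per_week: float = 1.06
    n_metrics: int = 300
    metric_corr: float = 0.6
    baseline_hazard: float = 0.002
    spike_coef: float = 0.8
    rest_gap_coef: float = 0.7
    target_injuries: float | None = 18.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_players < 0:
            raise ConfigError("n_players must be >= 0")
        if self.n_players > 0:
            total = sum(self.position_weights.values())
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ConfigError(f"position_weights sum to {total}, expected 1")
            if any(w < 0 for w in self.position_weights.values()):
                raise ConfigError("position_weights must be nonnegative")
        if not (0.0 < self.baseline_hazard < 1.0):
            raise ConfigError("baseline_hazard must lie in (0, 1)")
        if not (0.0 <= self.metric_corr < 1.0):
            raise ConfigError("metric_corr must lie in [0, 1)")
        if self.season_end < self.season_start and self.n_players > 0:
            raise ConfigError("season_end must not precede season_start")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["season_start"] = self.season_start.isoformat()
        d["season_end"] = self.season_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("season_start", "season_end"):
            if isinstance(d.get(key), str):
                d[key] = dt.date.fromisoformat(d[key])
        if d.get("position_weights") is not None:
            d["position_weights"] = dict(d["position_weights"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class SessionRecord:
    """One exercise-level measurement row for a player on a date."""

    player_id: str
    date: dt.date
    session_type: str  # "training" | "match"
    exercise_idx: int
    metrics: Mapping[str, float]
    descriptive: Mapping[str, object]


@dataclass
class InjuryLog:
    """Reported noncontact injuries: (player, date, match/training context)."""

    entries: list[tuple[str, dt.date, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["player_id", "date", "context"]
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = [d.isoformat() for d in df["date"]] if len(df) else df["date"]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InjuryLog":
        df = pd.read_csv(path)
        entries = [
            (str(r.player_id), dt.date.fromisoformat(str(r.date)), str(r.context))
            for r in df.itertuples()
        ]
        return cls(entries)


# ---------------------------------------------------------------------------
# metric schema


def metric_names(n_metrics: int) -> list[str]:
    """Deterministic GPS-like column names for ``n_metrics`` metrics.

    The pool cycles through the metric families a Catapult-style export
    contains (distances, loads, band counts, per-band maxima and averages,
    durations) so the aggregation-rule heuristics of :mod:`data_prep` are
    exercised.  Two quality columns (``hdop_avg``, ``sat_count_max``) are
    always present — they exist only to be dropped — and the tail of the
    list duplicates early columns under rescaled aliases so redundancy
    handling in mRMR has something to find.
    """
    if n_metrics <= 0:
        return []
    base = ["player_load", "total_duration_min", "hdop_avg", "sat_count_max"]
    fams = (
        "dist_band{k}_m",
        "load_axis{k}",
        "eff_band{k}_count",
        "max_vel_band{k}",
        "avg_accel_band{k}",
    )
    names = list(base[:n_metrics])
    k = 0
    while len(names) < n_metrics:
        names.append(fams[k % len(fams)].format(k=k // len(fams)))
        k += 1
    # rescaled duplicates of the leading informative columns (>= 8 metrics)
    n_dup = min(max(n_metrics // 20, 2), max(n_metrics - 8, 0))
    for j in range(n_dup):
        src = names[4 + j] if n_metrics > 4 + j else names[0]
        names[-(j + 1)] = f"dup{j}_of_{src}"
    return names


def _dup_source(name: str) -> str | None:
    if name.startswith("dup") and "_of_" in name:
        return name.split("_of_", 1)[1]
    return None


# ---------------------------------------------------------------------------
# hazard model


def injury_probability(
    load_history: Sequence[float], day_index: int, config: SimConfig
) -> float:
    """Per-day injury probability for an active day of one player.

    ``load_history`` is the player's daily-load series (zero on idle days).
    The hazard is ``baseline_hazard`` scaled up by ``exp(spike_coef * z+)``
    where ``z+`` is the positive z-score of today's load against the
    previous 14 days, and by ``exp(rest_gap_coef)`` when today is active
    after >= 2 consecutive idle days; the result is clipped to [0, 1].
    """
    loads = np.asarray(load_history, dtype=float)
    if np.any(loads < 0):
        raise ValueError("daily loads must be nonnegative")
    if not (0 <= day_index < len(loads)):
        raise IndexError("day_index outside load history")

    today = loads[day_index]
    prev = loads[max(0, day_index - 14) : day_index]
    z_spike = 0.0
    if prev.size >= 2:
        sd = float(np.std(prev, ddof=1))
        if sd > 0:
            z_spike = max((float(today) - float(np.mean(prev))) / sd, 0.0)

    rest_gap = (
        today > 0
        and day_index >= 2
        and loads[day_index - 1] == 0
        and loads[day_index - 2] == 0
    )

    log_mult = config.spike_coef * z_spike
    if rest_gap:
        log_mult += config.rest_gap_coef
    # cap the multiplier: the probability is clipped to 1 anyway
    p = config.baseline_hazard * np.exp(min(log_mult, 30.0))
    return float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# season generation


def _team_calendar(config: SimConfig, rng: np.random.Generator):
    """Schedule of (date, kind) team events over the season."""
    days = pd.date_range(config.season_start, config.season_end, freq="D")
    events: dict[dt.date, str] = {}
    extra_match_p = max(config.matches_per_week - 1.0, 0.0)
    for week_start in range(0, len(days), 7):
        week = days[week_start : week_start + 7]
        weekdays = {d.weekday(): d.date() for d in week}
        # one match at the weekend, occasionally a midweek fixture
        if 6 in weekdays:
            events[weekdays[6]] = "match"
        if 2 in weekdays and rng.random() < extra_match_p:
            events[weekdays[2]] = "match"
        train_pool = [wd for wd in sorted(weekdays) if events.get(weekdays[wd]) != "match"]
        n_train = min(config.sessions_per_week, len(train_pool))
        chosen = rng.choice(train_pool, size=n_train, replace=False) if n_train else []
        for wd in chosen:
            events[weekdays[wd]] = "training"
    return sorted(events.items())


def generate_season(config: SimConfig) -> tuple[pd.DataFrame, InjuryLog]:
    """Simulate one season.

    Returns the exercise-level session table (one row per player-exercise,
    columns = :data:`DESCRIPTIVE_COLS` + metric columns) and the injury log.
    Deterministic for a fixed config (``config.seed`` drives everything).
    """
    config.validate()
    names = metric_names(config.n_metrics)
    empty = pd.DataFrame(columns=list(DESCRIPTIVE_COLS) + names)
    if config.n_players == 0 or config.season_end < config.season_start:
        return empty, InjuryLog()

    rng = np.random.default_rng(config.seed)

    # players -----------------------------------------------------------
    pos_p = np.array([config.position_weights.get(p, 0.0) for p in POSITIONS])
    pos_p = pos_p / pos_p.sum()
    player_ids = [f"P{i:02d}" for i in range(1, config.n_players + 1)]
    positions = rng.choice(POSITIONS, size=config.n_players, p=pos_p)
    corridors = rng.choice(CORRIDORS, size=config.n_players)
    # age ~ 26.3 +/- 3.3 years at season start, tracked in months
    age0_months = np.round(rng.normal(26.3 * 12, 3.3 * 12, config.n_players)).astype(int)
    age0_months = np.clip(age0_months, 18 * 12, 38 * 12)

    calendar = _team_calendar(config, rng)
    all_days = pd.date_range(config.season_start, config.season_end, freq="D")
    day_pos = {d.date(): i for i, d in enumerate(all_days)}

    # per-metric log-scale parameters, fixed by the schema rng so column
    # identities are stable across seeds of the same shape
    schema_rng = np.random.default_rng(777)
    mu = schema_rng.uniform(1.0, 4.0, size=max(config.n_metrics, 1))
    sig = schema_rng.uniform(0.25, 0.6, size=max(config.n_metrics, 1))
    dup_scale = schema_rng.uniform(1.5, 4.0, size=max(config.n_metrics, 1))
    name_idx = {n: i for i, n in enumerate(names)}

    rows_desc: list[tuple] = []
    rows_metric: list[np.ndarray] = []
    sqrt_r = np.sqrt(config.metric_corr)
    sqrt_1r = np.sqrt(1.0 - config.metric_corr)

    match_meta: dict[dt.date, tuple[str, str, str]] = {}
    for date, kind in calendar:
        if kind == "match":
            match_meta[date] = (
                rng.choice(MATCH_RESULTS),
                rng.choice(MATCH_LOCATIONS),
                COMPETITIONS[0] if rng.random() < 0.85 else COMPETITIONS[1],
            )

    participation: dict[tuple[int, dt.date], int] = {}
    for pi in range(config.n_players):
        for date, kind in calendar:
            if kind == "match":
                active = rng.random() < 0.58  # matchday squad rotation
                n_ex = 1
            else:
                active = rng.random() < 0.88  # individual rest / recovery days
                n_ex = int(rng.integers(2, 6))
            if active:
                participation[(pi, date)] = n_ex

    for (pi, date), n_ex in participation.items():
        kind = "match" if date in match_meta else "training"
        # a match is one block whose workload tops a whole multi-exercise
        # training day (~3.5 exercises on average)
        intensity = 8.0 if kind == "match" else 1.0
        months = int(age0_months[pi] + (date - config.season_start).days // 30)
        result, location, competition = match_meta.get(date, ("", "", ""))
        for ex in range(1, n_ex + 1):
            f = rng.normal()
            eps = rng.normal(size=config.n_metrics)
            z = sqrt_r * f + sqrt_1r * eps
            vals = intensity * np.exp(mu + sig * z)
            # quality columns: narrow, load-independent
            if "hdop_avg" in name_idx:
                vals[name_idx["hdop_avg"]] = 1.0 + 0.5 * rng.random()
            if "sat_count_max" in name_idx:
                vals[name_idx["sat_count_max"]] = float(rng.integers(8, 13))
            if "total_duration_min" in name_idx:
                vals[name_idx["total_duration_min"]] = (
                    (95.0 if kind == "match" else 20.0 + 10.0 * rng.random()) / n_ex
                )
            for j, n in enumerate(names):
                src = _dup_source(n)
                if src is not None and src in name_idx:
                    vals[j] = vals[name_idx[src]] * dup_scale[j]
            rows_desc.append(
                (
                    player_ids[pi],
                    date,
                    kind,
                    ex,
                    positions[pi],
                    corridors[pi],
                    months,
                    date.strftime("%A"),
                    result,
                    location,
                    competition,
                )
            )
            rows_metric.append(vals)

    if not rows_desc:
        return empty, InjuryLog()

    desc = pd.DataFrame(rows_desc, columns=list(DESCRIPTIVE_COLS))
    metrics = pd.DataFrame(np.vstack(rows_metric), columns=names)
    sessions = pd.concat([desc, metrics], axis=1)
    sessions = sessions.sort_values(
        ["player_id", "date", "exercise_idx"], kind="stable"
    ).reset_index(drop=True)

    # injuries ----------------------------------------------------------
    load_col = "player_load" if "player_load" in names else names[0]
    daily_load = np.zeros((config.n_players, len(all_days)))
    pid_idx = {p: i for i, p in enumerate(player_ids)}
    grouped = sessions.groupby(["player_id", "date"], sort=False)[load_col].sum()
    for (pid, date), load in grouped.items():
        daily_load[pid_idx[pid], day_pos[date]] = load

    active_days = sorted(participation)
    hazards = np.array(
        [
            injury_probability(daily_load[pi], day_pos[date], config)
            for pi, date in active_days
        ]
    )
    if config.target_injuries is not None and hazards.sum() > 0:
        hazards = np.clip(hazards * config.target_injuries / hazards.sum(), 0, 1)

    draws = rng.random(len(active_days))
    log = InjuryLog()
    for (pi, date), h, u in zip(active_days, hazards, draws):
        if u < h:
            context = "match" if date in match_meta else "training"
            log.entries.append((player_ids[pi], date, context))
    log.entries.sort()
    return sessions, log


def write_sessions_csv(sessions: pd.DataFrame, path) -> None:
    out = sessions.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_sessions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["date"] = df["date"].map(lambda s: dt.date.fromisoformat(str(s)))
    return df
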