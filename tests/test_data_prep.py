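"""Aggregation, invalid-column dropping, dummy days, one-hot encoding."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from injurypred import data_prep
from injurypred.data_prep import (
    AggregationSpec,
    aggregate_sessions,
    drop_invalid_metrics,
    encode_descriptive,
    insert_dummy_days,
)

D = dt.date


def session_row(pid="P01", date=D(2021, 1, 1), stype="training", ex=1, **metrics):
    row = {
        "player_id": pid,
        "date": date,
        "session_type": stype,
        "exercise_idx": ex,
        "position": "forward",
        "corridor": "central",
        "age_months": 300,
        "day_of_week": date.strftime("%A"),
        "match_result": "win" if stype == "match" else "",
        "match_location": "home" if stype == "match" else "",
        "match_competition": "league" if stype == "match" else "",
    }
    row.update(metrics)
    return row


class TestAggregationSpec:
    @pytest.mark.parametrize(
        "name,rule",
        [
            ("max_vel_band3", "max"),
            ("peak_accel", "max"),
            ("avg_speed", "mean"),
            ("mean_hr", "mean"),
            ("dist_band2_m", "sum"),
            ("player_load", "sum"),
            ("eff_band1_count", "sum"),
        ],
    )
    def test_suffix_heuristic(self, name, rule):
        assert AggregationSpec().rule_for(name) == rule

    def test_explicit_rule_wins(self):
        spec = AggregationSpec(rules={"max_vel": "mean"})
        assert spec.rule_for("max_vel") == "mean"

    def test_yaml_round_trip(self, tmp_path):
        spec = AggregationSpec(rules={"a": "max"}, default="sum")
        spec.to_yaml(tmp_path / "spec.yaml")
        back = AggregationSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.rules == spec.rules and back.default == spec.default


class TestAggregateSessions:
    def test_sum_and_max(self):
        df = pd.DataFrame(
            [
                session_row(ex=1, distance=3.0, max_vel=6.1),
                session_row(ex=2, distance=4.0, max_vel=7.2),
            ]
        )
        out = aggregate_sessions(df)
        assert len(out) == 1
        assert out.loc[0, "distance"] == 7.0
        assert out.loc[0, "max_vel"] == 7.2
        assert out.loc[0, "n_exercises"] == 2

    def test_mixed_spec_brute_force(self):
        """5-exercise day equals independent per-function recomputation."""
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, 10.0, size=(5, 3))
        df = pd.DataFrame(
            [
                session_row(ex=i + 1, load=vals[i, 0], max_v=vals[i, 1], avg_r=vals[i, 2])
                for i in range(5)
            ]
        )
        out = aggregate_sessions(df)
        assert out.loc[0, "load"] == pytest.approx(vals[:, 0].sum())
        assert out.loc[0, "max_v"] == pytest.approx(vals[:, 1].max())
        assert out.loc[0, "avg_r"] == pytest.approx(vals[:, 2].mean())

    def test_permutation_invariance(self):
        rows = [session_row(ex=i, load=float(i * 3 + 1), max_v=float(10 - i)) for i in range(4)]
        a = aggregate_sessions(pd.DataFrame(rows))
        b = aggregate_sessions(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_match_identity_dominates(self):
        df = pd.DataFrame(
            [
                session_row(stype="training", ex=1, load=1.0),
                session_row(stype="match", ex=2, load=2.0),
            ]
        )
        out = aggregate_sessions(df)
        assert out.loc[0, "session_type"] == "match"
        assert out.loc[0, "match_result"] == "win"

    def test_row_key_uniqueness(self):
        df = pd.DataFrame(
            [
                session_row(pid="P01", date=D(2021, 1, 1), ex=1, load=1.0),
                session_row(pid="P01", date=D(2021, 1, 1), ex=2, load=1.0),
                session_row(pid="P01", date=D(2021, 1, 2), ex=1, load=1.0),
                session_row(pid="P02", date=D(2021, 1, 1), ex=1, load=1.0),
            ]
        )
        out = aggregate_sessions(df)
        assert not out.duplicated(subset=["player_id", "date"]).any()
        assert len(out) == 3


class TestDropInvalidMetrics:
    def table(self):
        return pd.DataFrame(
            {
                "player_id": ["P01"],
                "date": [D(2021, 1, 1)],
                "load": [5.0],
                "hdop_avg": [1.1],
            }
        )

    def test_pattern_dropped(self):
        out = drop_invalid_metrics(self.table(), ["hdop"])
        assert "hdop_avg" not in out.columns and "load" in out.columns

    def test_all_missing_dropped(self):
        t = self.table()
        t["broken_sensor"] = np.nan
        out = drop_invalid_metrics(t, ["hdop"])
        assert "broken_sensor" not in out.columns

    def test_hand_enumerated_fixture(self):
        t = pd.DataFrame(
            {
                "player_id": ["P01", "P02"],
                "date": [D(2021, 1, 1)] * 2,
                "load": [1.0, 2.0],
                "dist": [3.0, 4.0],
                "hdop_avg": [1.0, 1.1],
                "sat_count_max": [9.0, 10.0],
                "max_vel": [5.0, 6.0],
                "duration": [60.0, 70.0],
            }
        )
        out = drop_invalid_metrics(t, ["hdop", "sat_count"])
        kept = data_prep.metric_columns(out)
        assert sorted(kept) == ["dist", "duration", "load", "max_vel"]

    def test_all_dropped_is_error(self):
        t = self.table().drop(columns=["load"])
        with pytest.raises(ValueError):
            drop_invalid_metrics(t, ["hdop"])

    def test_empty_patterns_rejected(self):
        with pytest.raises(ValueError):
            drop_invalid_metrics(self.table(), [])


class TestInsertDummyDays:
    def base(self):
        return pd.DataFrame(
            [
                {"player_id": "P01", "date": D(2021, 1, 1), "load": 5.0, "injury": 0},
                {"player_id": "P01", "date": D(2021, 1, 3), "load": 7.0, "injury": 1},
            ]
        )

    def test_missing_day_inserted_as_zeros(self):
        out = insert_dummy_days(self.base(), D(2021, 1, 1), D(2021, 1, 3))
        day2 = out[(out.player_id == "P01") & (out.date == D(2021, 1, 2))]
        assert len(day2) == 1
        assert day2.iloc[0]["load"] == 0
        assert day2.iloc[0]["is_dummy"] == 1
        assert day2.iloc[0]["injury"] == 0

    def test_full_calendar_is_noop(self):
        t = self.base()
        t.loc[len(t)] = {"player_id": "P01", "date": D(2021, 1, 2), "load": 1.0, "injury": 0}
        out = insert_dummy_days(t, D(2021, 1, 1), D(2021, 1, 3))
        assert len(out) == 3
        assert (out.is_dummy == 0).all()

    def test_row_count_oracle(self):
        """3 players x 10-day calendar -> exactly 30 rows."""
        rng = np.random.default_rng(1)
        rows = []
        for p in range(3):
            days = rng.choice(10, size=rng.integers(2, 6), replace=False)
            for d in days:
                rows.append(
                    {"player_id": f"P{p}", "date": D(2021, 1, 1) + dt.timedelta(int(d)), "load": 1.0, "injury": 0}
                )
        t = pd.DataFrame(rows)
        out = insert_dummy_days(t, D(2021, 1, 1), D(2021, 1, 10))
        assert len(out) == 30
        assert not out.duplicated(subset=["player_id", "date"]).any()

    def test_original_rows_untouched(self):
        out = insert_dummy_days(self.base(), D(2021, 1, 1), D(2021, 1, 3))
        orig = out[out.is_dummy == 0]
        assert orig["load"].tolist() == [5.0, 7.0]
        assert orig["injury"].tolist() == [0, 1]

    def test_bad_calendar_rejected(self):
        with pytest.raises(ValueError):
            insert_dummy_days(self.base(), D(2021, 1, 5), D(2021, 1, 1))


class TestEncodeDescriptive:
    def test_one_hot_completeness(self):
        t = pd.DataFrame(
            {
                "player_id": ["P1", "P1", "P2"],
                "date": [D(2021, 1, 1), D(2021, 1, 2), D(2021, 1, 1)],
                "session_type": ["training", "match", ""],
                "is_dummy": [0, 0, 1],
                "load": [1.0, 2.0, 0.0],
            }
        )
        out = encode_descriptive(t, ["session_type"])
        cols = ["session_type=match", "session_type=training"]
        assert all(c in out.columns for c in cols)
        sums = out[cols].sum(axis=1)
        assert sums[out.is_dummy == 0].eq(1).all()
        assert sums[out.is_dummy == 1].eq(0).all()

    def test_level_count_oracle(self):
        """Categoricals with 2, 3 and 5 levels -> 10 indicator columns."""
        rng = np.random.default_rng(2)
        t = pd.DataFrame(
            {
                "player_id": [f"P{i}" for i in range(30)],
                "date": [D(2021, 1, 1)] * 30,
                "a": rng.choice(["x", "y"], 30),
                "b": rng.choice(["u", "v", "w"], 30),
                "c": rng.choice(list("abcde"), 30),
            }
        )
        # ensure all levels observed
        t.loc[:1, "a"] = ["x", "y"]
        t.loc[:2, "b"] = ["u", "v", "w"]
        t.loc[:4, "c"] = list("abcde")
        out = encode_descriptive(t, ["a", "b", "c"])
        indicators = [c for c in out.columns if "=" in c]
        assert len(indicators) == 10

    def test_known_levels_give_zero_columns(self):
        t = pd.DataFrame(
            {
                "player_id": ["P1"],
                "date": [D(2021, 1, 1)],
                "position": ["forward"],
            }
        )
        out = encode_descriptive(
            t, ["position"], known_levels={"position": ["forward", "defender"]}
        )
        assert out["position=defender"].tolist() == [0]
        assert out["position=forward"].tolist() == [1]


def test_player_day_csv_round_trip(tmp_path, player_table):
    path = tmp_path / "pd.csv"
    data_prep.write_player_day_csv(player_table, path)
    back = data_prep.read_player_day_csv(path)
    pd.testing.assert_frame_equal(player_table, back, check_dtype=False)


def test_build_player_day_table_shape(small_cfg, player_table):
    n_days = (small_cfg.season_end - small_cfg.season_start).days + 1
    assert len(player_table) == small_cfg.n_players * n_days
    assert not player_table.duplicated(subset=["player_id", "date"]).any()
    assert set(player_table.injury.unique()) <= {0, 1}
    # quality columns removed, one-hot groups present
    assert not any("hdop" in c for c in player_table.columns)
    assert any(c.startswith("position=") for c in player_table.columns)
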