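import datetime as dt

import numpy as np
import pandas as pd
import pytest

import injurypred as ip


@pytest.fixture(scope="session")
def small_cfg() -> ip.SimConfig:
    """A compact season with a strong, learnable load-spike hazard."""
    return ip.SimConfig(
        n_players=20,
        season_start=dt.date(2020, 9, 7),
        season_end=dt.date(2021, 1, 3),
        n_metrics=25,
        target_injuries=20.0,
        spike_coef=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_season(small_cfg):
    return ip.generate_season(small_cfg)


@pytest.fixture(scope="session")
def player_table(small_cfg, small_season):
    sessions, log = small_season
    return ip.build_player_day_table(
        sessions, log, small_cfg.season_start, small_cfg.season_end
    )


@pytest.fixture(scope="session")
def prepared(player_table):
    return ip.preprocess_and_rank(player_table)


def toy_player_days(n_players=6, n_days=30, n_injured=3, seed=0) -> pd.DataFrame:
    """Small hand-built player-day table with numeric features and labels."""
    rng = np.random.default_rng(seed)
    rows = []
    start = dt.date(2021, 1, 1)
    for p in range(n_players):
        for d in range(n_days):
            rows.append(
                {
                    "player_id": f"P{p:02d}",
                    "date": start + dt.timedelta(days=d),
                    "load": float(rng.gamma(3.0, 50.0)),
                    "dist": float(rng.gamma(2.0, 100.0)),
                    "is_dummy": 0,
                    "injury": 0,
                }
            )
    df = pd.DataFrame(rows)
    injured_players = rng.choice(n_players, size=n_injured, replace=False)
    for p in injured_players:
        day = int(rng.integers(0, n_days))
        idx = df.index[(df.player_id == f"P{p:02d}")][day]
        df.loc[idx, "injury"] = 1
        df.loc[idx, "load"] *= 2.5  # injuries follow load spikes
    return df
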