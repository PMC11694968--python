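"""Build the player-day feature table from the simulated session records.

Aggregates exercise rows per (player, date), drops GPS-quality columns,
attaches injury labels, inserts all-zero dummy days for a continuous
calendar, and one-hot encodes the descriptive variables.
"""

from pathlib import Path

from injurypred import data_prep, synthetic

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sessions = synthetic.read_sessions_csv(OUT / "sessions.csv")
    log = synthetic.InjuryLog.from_csv(OUT / "injuries.csv")
    cfg = synthetic.SimConfig.from_yaml(OUT / "sim_config.yaml")
    table = data_prep.build_player_day_table(
        sessions, log, cfg.season_start, cfg.season_end
    )
    data_prep.write_player_day_csv(table, OUT / "player_days.csv")
    n_feat = len(data_prep.feature_columns(table))
    print(
        f"{len(table)} player-day rows ({table.is_dummy.sum()} dummy days), "
        f"{n_feat} feature columns, {table.injury.sum()} injury days "
        f"-> {OUT / 'player_days.csv'}"
    )


if __name__ == "__main__":
    main()
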