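"""Generate the synthetic season used by the downstream analyses.

Emulates the study cohort (34 players, five positions, 36-week calendar
with ~6 training sessions and ~1 match per week, ~18 injuries at ~0.2% of
player-days) with a reduced metric panel (60 GPS-like columns) to keep the
written CSVs small.  Writes sessions, injury log, config and the injury
context summary under results/.
"""

import json
from pathlib import Path

import injurypred as ip
from injurypred import synthetic
from injurypred.experiment import injury_context_summary

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = ip.SimConfig(n_metrics=60, seed=SEED)
    sessions, log = ip.generate_season(cfg)
    synthetic.write_sessions_csv(sessions, OUT / "sessions.csv")
    log.to_csv(OUT / "injuries.csv")
    cfg.to_yaml(OUT / "sim_config.yaml")
    ctx = injury_context_summary(log)
    with open(OUT / "injury_context.json", "w") as fh:
        json.dump(ctx, fh, indent=1)
    n_match_days = sessions.loc[sessions.session_type == "match", "date"].nunique()
    n_train_days = sessions.loc[sessions.session_type == "training", "date"].nunique()
    print(
        f"season {cfg.season_start}..{cfg.season_end}: "
        f"{len(sessions)} exercise rows, {n_train_days} training days, "
        f"{n_match_days} match days"
    )
    print(
        f"{ctx['n_injuries']} injuries ({ctx['pct_match']}% in matches, "
        f"{ctx['pct_training']}% in training) -> {OUT}/"
    )


if __name__ == "__main__":
    main()
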