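"""Run the model x learning-mode x top-p sweep on the prepared season.

The full protocol (500 repetitions per coordinate, 78 000 runs) is
reproduced at reduced scale here: 5 repetitions over the p-grid up to the
available feature count.  Each run redraws the player-disjoint folds,
undersamples the training split with k-means centroids, trains, picks the
ROC-elbow threshold on the training scores and evaluates both splits.
"""

from pathlib import Path

from injurypred import data_prep, experiment, feature_select

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
REPETITIONS = 5


def main() -> None:
    table = data_prep.read_player_day_csv(OUT / "prepared_table.csv")
    ranking = feature_select.FeatureRanking.from_csv(OUT / "ranking.csv")
    grid = experiment.SweepGrid(
        p_grid=tuple(feature_select.p_grid(len(ranking))),
        repetitions=REPETITIONS,
        base_seed=SEED,
    )
    agg, raw = experiment.run_sweep(table, ranking, grid)
    agg.to_csv(OUT / "sweep.csv", index=False)
    raw.to_csv(OUT / "sweep_raw.csv", index=False)
    print(
        f"{grid.total_runs} runs ({grid.n_configurations} configurations x "
        f"{REPETITIONS} repetitions, 2 folds each) -> {OUT / 'sweep.csv'}"
    )


if __name__ == "__main__":
    main()
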