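"""Winsorize, standardize and rank the features by mRMR.

Outlier bounds come from the injured rows only; clipping and z-scoring
apply to the whole table; zero-variance columns are removed; the rest are
put in greedy mRMR order (F-statistic relevance / mean |corr| redundancy).
"""

from pathlib import Path

from injurypred import data_prep, pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = data_prep.read_player_day_csv(OUT / "player_days.csv")
    prep = pipeline.preprocess_and_rank(table)
    prep.ranking.to_csv(OUT / "ranking.csv")
    data_prep.write_player_day_csv(prep.table, OUT / "prepared_table.csv")
    prep.bounds.to_json(OUT / "winsor_bounds.json")
    prep.standardizer.to_json(OUT / "standardizer.json")
    top = ", ".join(prep.ranking.names[:5])
    print(
        f"{len(prep.ranking)} features ranked "
        f"({len(prep.removed_zero_variance)} zero-variance removed); "
        f"top 5: {top}"
    )


if __name__ == "__main__":
    main()
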