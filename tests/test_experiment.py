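"""Sweep harness: run counts, aggregation, selection, reporting."""

import numpy as np
import pandas as pd
import pytest

import injurypred as ip
from injurypred import experiment
from injurypred.experiment import (
    SweepGrid,
    aggregate_records,
    derive_seed,
    injury_context_summary,
    permute_labels,
    records_to_frame,
    run_config,
    run_sweep,
    select_best,
)
from injurypred.models import UndersampleConfig


class TestSweepGrid:
    def test_protocol_cardinality(self):
        """3 models x 2 modes x 26 p-values x 500 reps = 78 000 runs."""
        grid = SweepGrid(repetitions=500)
        assert grid.n_configurations == 156
        assert grid.total_runs == 78_000

    def test_tiny_grid(self):
        grid = SweepGrid(models=("svm",), modes=(True,), p_grid=(10,), repetitions=5)
        assert grid.total_runs == 5
        assert sum(1 for _ in grid.iter_runs()) == 5

    def test_enumeration_matches_invariant(self):
        grid = SweepGrid(models=("svm", "fnn"), p_grid=(10, 20, 30), repetitions=4)
        assert sum(1 for _ in grid.iter_runs()) == grid.total_runs == 2 * 2 * 3 * 4


class TestDeriveSeed:
    def test_stable_and_bounded(self):
        s = derive_seed(42, "svm", True, 10, 3)
        assert s == derive_seed(42, "svm", True, 10, 3)
        assert 0 <= s < 2**31

    def test_coordinates_change_seed(self):
        assert derive_seed(1, "svm", True, 10, 0) != derive_seed(1, "svm", True, 10, 1)
        assert derive_seed(1, "svm", True, 10, 0) != derive_seed(2, "svm", True, 10, 0)


class TestRunConfig:
    def test_record_counts_and_determinism(self, prepared):
        recs = run_config(
            prepared.table, prepared.ranking, "adaboost", True, 10,
            repetitions=2, base_seed=5,
        )
        assert len(recs) == 4  # 2 reps x 2 folds
        assert {r.fold for r in recs} == {1, 2}
        seeds = {r.seed for r in recs}
        assert len(seeds) == 2  # one seed per repetition
        again = run_config(
            prepared.table, prepared.ranking, "adaboost", True, 10,
            repetitions=2, base_seed=5,
        )
        assert records_to_frame(recs).equals(records_to_frame(again))

    def test_threshold_transferred_from_train(self, prepared):
        recs = run_config(
            prepared.table, prepared.ranking, "adaboost", True, 10,
            repetitions=1, base_seed=0,
        )
        for r in recs:
            assert r.test.threshold == r.train.threshold

    def test_p_exceeding_features_error(self, prepared):
        with pytest.raises(ValueError):
            run_config(
                prepared.table, prepared.ranking, "svm", True,
                len(prepared.ranking) + 10, repetitions=1,
            )


class TestAggregation:
    def test_mean_sd_recomputable_from_records(self, prepared):
        recs = run_config(
            prepared.table, prepared.ranking, "adaboost", True, 10,
            repetitions=3, base_seed=2,
        )
        raw = records_to_frame(recs)
        agg = aggregate_records(raw)
        assert len(agg) == 1
        row = agg.iloc[0]
        assert row["n_runs"] == 6
        assert row["test_auc_mean"] == pytest.approx(raw["test_auc"].mean())
        assert row["test_auc_std"] == pytest.approx(raw["test_auc"].std())
        assert row["train_gmean_mean"] == pytest.approx(raw["train_gmean"].mean())


class TestRunSweep:
    def test_run_count_identity_and_aggregate(self, prepared):
        grid = SweepGrid(
            models=("adaboost",), modes=(True, False), p_grid=(10, 20),
            repetitions=2, base_seed=1,
        )
        agg, raw = run_sweep(prepared.table, prepared.ranking, grid)
        assert len(raw) == grid.total_runs * 2
        assert len(agg) == grid.n_configurations
        assert (agg["n_runs"] == 4).all()

    def test_empty_grid_error(self, prepared):
        with pytest.raises(ValueError):
            run_sweep(prepared.table, prepared.ranking, SweepGrid(repetitions=0))


class TestSelectBest:
    def agg_fixture(self):
        rows = []
        rng = np.random.default_rng(0)
        for model in ("svm", "adaboost"):
            for cs in (True, False):
                for p in (10, 20, 30):
                    rows.append(
                        {
                            "model": model,
                            "cost_sensitive": cs,
                            "p": p,
                            "train_gmean_mean": rng.random(),
                            "test_gmean_mean": rng.random(),
                            "train_sensitivity_mean": rng.random(),
                            "test_sensitivity_mean": rng.random(),
                            "test_specificity_mean": rng.random(),
                            "test_auc_mean": rng.random(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_single_row(self):
        df = self.agg_fixture().iloc[[0]]
        rep = select_best(df)
        assert rep.overall["p"] == int(df.iloc[0]["p"])

    def test_tie_prefers_smaller_p(self):
        df = self.agg_fixture().iloc[:3].copy()
        df["train_gmean_mean"] = 0.9
        rep = select_best(df)
        assert rep.overall["p"] == 10

    def test_matches_exhaustive_argmax_oracle(self):
        df = self.agg_fixture()
        rep = select_best(df)
        for g in rep.groups:
            sub = df[(df.model == g["model"]) & (df.cost_sensitive == g["cost_sensitive"])]
            assert g["train_gmean"] == pytest.approx(sub["train_gmean_mean"].max())
            best_rows = sub[sub.train_gmean_mean == sub.train_gmean_mean.max()]
            assert g["p"] == int(best_rows["p"].min())
        test_gs = [g["test_gmean"] for g in rep.groups]
        assert test_gs == sorted(test_gs, reverse=True)
        assert rep.overall == rep.groups[0]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_best(pd.DataFrame())


class TestReporting:
    def test_injury_context_study_counts(self):
        """18 injuries with 10 in matches -> 55.56% match-related."""
        import datetime as dt

        entries = [
            (f"P{i:02d}", dt.date(2021, 1, 1) + dt.timedelta(days=i),
             "match" if i < 10 else "training")
            for i in range(18)
        ]
        summary = injury_context_summary(ip.InjuryLog(entries))
        assert summary["n_injuries"] == 18
        assert summary["pct_match"] == 55.56
        assert summary["pct_training"] == 44.44

    def test_permute_labels_preserves_count(self, player_table):
        permuted = permute_labels(player_table, seed=1)
        assert permuted["injury"].sum() == player_table["injury"].sum()
        assert not permuted["injury"].equals(player_table["injury"])


class TestPipelinePrep:
    def test_prepared_dataset_properties(self, prepared):
        t = prepared.table
        feats = prepared.features
        assert len(prepared.ranking) == len(feats)
        # standardized on the fit table
        sub = t[feats].to_numpy()
        assert np.nanmax(np.abs(sub.mean(axis=0))) < 1e-9
        # no zero-variance feature survives
        assert (t[feats].nunique() > 1).all()

    def test_leakage_free_variant_runs(self, player_table):
        from injurypred.pipeline import run_config_leakage_free

        recs = run_config_leakage_free(
            player_table, "adaboost", True, 10, repetitions=1, base_seed=0
        )
        assert len(recs) == 2
        for r in recs:
            assert 0 <= r.test.auc <= 1
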