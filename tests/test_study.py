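import numpy as np
import pandas as pd
import pytest

import ucnmr as u
from ucnmr.processing import BucketTable
from ucnmr.study import STANDARD_CONTRASTS


def _metadata(rows):
    defaults = {"timepoint": "baseline", "uceis": 2, "nancy": 1, "sccai": 2}
    records = []
    for i, row in enumerate(rows):
        rec = {"sample_id": f"S{i:03d}", "subject_id": f"P{i:03d}", **defaults, **row}
        records.append(rec)
    return pd.DataFrame(records)


class TestContrastLabels:
    def test_uceis_threshold_boundary(self):
        meta = _metadata([{"uceis": 3}, {"uceis": 4}])
        labels, excluded = u.assign_contrast_labels(meta, "uceis")
        assert labels["S000"] == "low"
        assert labels["S001"] == "high"
        assert excluded == []

    def test_nancy_grade_two_excluded(self):
        meta = _metadata([{"nancy": 0}, {"nancy": 2}, {"nancy": 3}])
        labels, excluded = u.assign_contrast_labels(meta, "nancy")
        assert labels["S000"] == "low" and labels["S002"] == "high"
        assert excluded[0][0] == "S001"

    def test_delta_rule_and_nochange_exclusion(self):
        meta = _metadata([
            {"subject_id": "A", "uceis": 5},
            {"subject_id": "A", "uceis": 3, "timepoint": "followup", "sample_id": "F0"},
            {"subject_id": "B", "uceis": 2},
            {"subject_id": "B", "uceis": 4, "timepoint": "followup", "sample_id": "F1"},
            {"subject_id": "C", "uceis": 3},
            {"subject_id": "C", "uceis": 3, "timepoint": "followup", "sample_id": "F2"},
        ])
        meta.loc[1, "sample_id"] = "F0"
        labels, excluded = u.assign_contrast_labels(meta, "delta_uceis")
        assert labels["S000"] == "improved"
        assert labels["S002"] == "worsened"
        assert ("S004", "no change in score") in excluded

    def test_missing_score_rejected_naming_sample(self):
        meta = _metadata([{"uceis": np.nan}])
        with pytest.raises(ValueError, match="S000"):
            u.assign_contrast_labels(meta, "uceis")

    def test_partitions_match_study_marginals(self):
        """A cohort built to the study's marginal counts labels 24/16 and
        trichotomizes outcomes, with histology grade 2 removed."""
        rng = np.random.default_rng(0)
        spectra, meta = u.simulate_longitudinal_study(
            cohort=u.CohortSpec(noise_sd=0.0, shift_jitter_sd=0.0, global_shift_sd=0.0,
                                baseline_drift_amplitude=0.0, master_seed=4),
            acq=u.AcquisitionSpec(n_points=4096), rng=rng,
        )
        uceis_labels, _ = u.assign_contrast_labels(meta, "uceis")
        assert uceis_labels.value_counts()["low"] == 24
        assert uceis_labels.value_counts()["high"] == 16
        delta_labels, excluded = u.assign_contrast_labels(meta, "delta_uceis")
        assert delta_labels.value_counts()["improved"] == 18
        assert delta_labels.value_counts()["worsened"] == 15
        assert sum(1 for _, r in excluded if r == "no change in score") == 7
        nancy_labels, nancy_excluded = u.assign_contrast_labels(meta, "nancy")
        assert all(meta.set_index("sample_id").loc[s, "nancy"] == 2
                   for s, _ in nancy_excluded)


class TestNoChangeGroup:
    def _model_and_rows(self, y_targets):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 20))
        y = np.array(["improved"] * 15 + ["worsened"] * 15)
        X[:, 2] += np.where(y == "worsened", 6.0, 0.0)
        sd = X.std(axis=0, ddof=1)
        Xs = (X - X.mean(axis=0)) / np.sqrt(sd)
        model = u.fit_oplsda(Xs, y, rng=rng, positive_class="worsened")
        direction = model.w * model.c
        rows = np.array([
            direction * (t - model.y_mean) / (direction @ direction) for t in y_targets
        ])
        return model, rows

    def test_printed_counts_give_71_percent(self):
        thr = 0.5
        model, rows = self._model_and_rows([thr] * 5 + [1.4, 1.4])
        model.decision_threshold = thr
        table = BucketTable(values=np.abs(rows) + 1.0, bucket_centers=np.arange(20.0),
                            sample_ids=[f"n{i}" for i in range(7)], scaled=False)
        table.values = rows  # predictions bypass scaling (model.scaler is None)
        calls, acc = u.evaluate_nochange_group(model, table, [f"n{i}" for i in range(7)])
        assert calls["borderline"].sum() == 5
        assert (calls["call"][~calls["borderline"]] == "worsened").all()
        assert acc == 71

    def test_all_borderline_is_perfect(self):
        model, rows = self._model_and_rows([0.5] * 4)
        model.decision_threshold = 0.5
        table = BucketTable(values=rows, bucket_centers=np.arange(20.0),
                            sample_ids=["a", "b", "c", "d"], scaled=True)
        _, acc = u.evaluate_nochange_group(model, table, ["a", "b", "c", "d"])
        assert acc == 100

    def test_no_correct_calls_is_zero(self):
        model, rows = self._model_and_rows([1.5, 1.5, -0.6, -0.6])
        model.decision_threshold = 0.5
        table = BucketTable(values=rows, bucket_centers=np.arange(20.0),
                            sample_ids=["a", "b", "c", "d"], scaled=True)
        _, acc = u.evaluate_nochange_group(model, table, ["a", "b", "c", "d"])
        assert acc == 0

    def test_empty_group_rejected(self):
        model, rows = self._model_and_rows([0.5])
        table = BucketTable(values=rows, bucket_centers=np.arange(20.0),
                            sample_ids=["a"], scaled=True)
        with pytest.raises(ValueError):
            u.evaluate_nochange_group(model, table, [])


class TestDemographics:
    def test_study_medication_counts_significant(self):
        # 5 of 24 vs 9 of 16 exposed: chi-squared with continuity correction
        meta = _metadata([{"med": 1} for _ in range(5)] + [{"med": 0} for _ in range(19)]
                         + [{"med": 1} for _ in range(9)] + [{"med": 0} for _ in range(7)])
        labels = pd.Series(["low"] * 24 + ["high"] * 16,
                           index=meta["sample_id"], name="uceis")
        out = u.compare_demographics(meta, labels, ["med"])
        assert out.loc[0, "p"] < 0.05

    def test_identical_distributions_not_significant(self):
        meta = _metadata([{"med": i % 2} for i in range(40)])
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=meta["sample_id"])
        out = u.compare_demographics(meta, labels, ["med"])
        assert out.loc[0, "p"] > 0.9

    def test_two_by_two_matches_hand_oracle(self):
        # [[10,0],[0,10]] with Yates: 4 * (|10-5| - 0.5)^2 / 5 = 16.2
        meta = _metadata([{"med": 1} for _ in range(10)] + [{"med": 0} for _ in range(10)])
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=meta["sample_id"])
        out = u.compare_demographics(meta, labels, ["med"])
        assert out.loc[0, "chi2"] == pytest.approx(16.2)

    def test_single_level_field_skipped(self):
        meta = _metadata([{"med": 1} for _ in range(10)])
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=meta["sample_id"])
        out = u.compare_demographics(meta, labels, ["med"])
        assert "skipped" in out.loc[0, "note"]


class TestCorrelationScreen:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=30)})
        out = u.correlation_screen(x, x)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_null_screen_calibration(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(50, 10)),
                             columns=[f"f{i}" for i in range(10)])
        clin = pd.DataFrame(rng.normal(size=(50, 10)),
                            columns=[f"c{i}" for i in range(10)])
        out = u.correlation_screen(feats, clin)
        assert (out["p"] < 0.05).sum() <= 15  # ~5 expected of 100
        # BH-adjusted flags should essentially vanish under the null
        assert out["significant"].sum() <= 1

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=25)
        b = 0.3 * a + rng.normal(size=25)
        r1 = u.correlation_screen(pd.DataFrame({"a": a}), pd.DataFrame({"b": b}))
        r2 = u.correlation_screen(pd.DataFrame({"a": 7 * a - 2}),
                                  pd.DataFrame({"b": -3 * b + 11}))
        assert abs(r1.loc[0, "r"]) == pytest.approx(abs(r2.loc[0, "r"]))

    def test_constant_variable_reported_undefined(self):
        out = u.correlation_screen(pd.DataFrame({"a": np.ones(10)}),
                                   pd.DataFrame({"b": np.arange(10.0)}))
        assert np.isnan(out.loc[0, "r"])
        assert "constant" in out.loc[0, "note"]


class TestAugmentedCheck:
    def test_noise_columns_change_little_and_deterministic(self):
        rng = np.random.default_rng(0)
        values = rng.random((40, 30)) + 0.5
        values[:, 0] += np.where(np.arange(40) < 24, 0.0, 1.5)
        table = BucketTable(values=values, bucket_centers=np.arange(30.0),
                            sample_ids=[f"s{i}" for i in range(40)])
        labels = np.array(["low"] * 24 + ["high"] * 16)
        clin = pd.DataFrame(rng.normal(size=(40, 3)), columns=["c1", "c2", "c3"])
        pol = u.CVPolicy(n_repetitions=15)
        out1 = u.augmented_model_check(table, clin, labels, pol,
                                       np.random.default_rng(5), positive_label="high")
        out2 = u.augmented_model_check(table, clin, labels, pol,
                                       np.random.default_rng(5), positive_label="high")
        assert out1["delta"] == out2["delta"]
        base_sd = out1["baseline"].accuracy.std(ddof=1)
        assert abs(out1["delta"]) < 2 * base_sd


class TestRunStudy:
    def test_smoke_profile_produces_full_report(self, tmp_path):
        config = {
            "seed": 6,
            "simulation": {"n_points": 4096},
            "cv": {"n_repetitions": 10},
            "contrasts": ["uceis", "nancy", "delta_uceis", "sccai"],
        }
        report = u.run_study(config, output_dir=tmp_path)
        assert set(report.contrasts) == {"uceis", "nancy", "delta_uceis", "sccai"}
        for name in ("uceis", "nancy", "delta_uceis"):
            block = report.contrasts[name]
            if block.get("skipped"):
                continue
            assert block["ks"].p_value >= 0.0
            assert block["variable_report"] is not None
        assert (tmp_path / "contrast_summary.csv").exists()
        assert (tmp_path / "pca_scores.csv").exists()
        assert report.correlations is not None
        assert report.nochange is not None and 0 <= report.nochange["accuracy_percent"] <= 100

    def test_missing_config_file_named_in_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.yml"):
            u.run_study(tmp_path / "nope.yml")
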