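"""Labeling, series assembly, SVM-RFE selection, CV, EFS, and reports."""

import numpy as np
import pandas as pd
import pytest

from gradiomics import (
    CohortSpec,
    SeriesSpec,
    assign_response_label,
    build_series_matrix,
    compute_metrics,
    cross_validate,
    efs_model,
    make_feature_cohort,
    report_feature_stats,
    rfe_frequency_select,
    run_all_individual_models,
)
from gradiomics.modeling import MODEL_NAMES, CohortTable, StratificationError
from gradiomics.gradients import FEATURE_NAMES


@pytest.fixture(scope="module")
def small_cohort():
    """Fast cohort for structural modeling checks (2 planted features)."""
    return make_feature_cohort(CohortSpec(
        n_lesions=40, class_balance=0.5, seed=5,
        planted_features={"core_GM_mean": 2.5, "oct_RAS_RG_mean": 2.5}))


class TestResponseLabel:
    @pytest.mark.parametrize("initial,followup,expected", [
        (1000.0, 799.0, "responder"),       # just past 20% reduction
        (1000.0, 800.0, "non_responder"),   # exactly at 80% stays non-responder
        (1000.0, 1500.0, "non_responder"),  # growth
    ])
    def test_threshold_rule(self, initial, followup, expected):
        assert assign_response_label(initial, followup) == expected

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            assign_response_label(0.0, 10.0)
        with pytest.raises(ValueError):
            assign_response_label(10.0, -1.0)


class TestSeriesMatrices:
    @pytest.mark.parametrize("series,n_cols", [
        ("A", 9), ("B", 9), ("C", 9), ("D", 72), ("E", 90),
    ])
    def test_pool_sizes(self, small_cohort, series, n_cols):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series=series))
        assert X.shape == (40, n_cols)
        assert set(np.unique(y)) == {0, 1}

    def test_series_c_is_core_over_margin(self, small_cohort):
        X, _ = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="C"))
        df = small_cohort.features["mri1"]
        expected = df["core_GM_mean"] / df["margin_GM_mean"]
        np.testing.assert_allclose(X["ratio_GM_mean"].to_numpy(), expected.to_numpy())

    def test_series_c_guards_zero_denominator(self, small_cohort):
        cohort = make_feature_cohort(CohortSpec(n_lesions=20, class_balance=0.5, seed=6))
        cohort.features["mri1"].loc[cohort.features["mri1"].index[0], "margin_GM_mean"] = 0.0
        X, _ = build_series_matrix(cohort, SeriesSpec(mode="mri1", series="C"))
        assert np.isnan(X["ratio_GM_mean"].iloc[0])

    def test_delta_of_identical_scans_is_zero(self):
        cohort = make_feature_cohort(CohortSpec(n_lesions=20, class_balance=0.5, seed=7))
        cohort.features["mri2"] = cohort.features["mri1"].copy()
        cohort.features["delta"] = cohort.features["mri2"] - cohort.features["mri1"]
        X, _ = build_series_matrix(cohort, SeriesSpec(mode="delta", series="E"))
        assert np.all(X.to_numpy() == 0.0)

    def test_missing_mode_raises(self, small_cohort):
        solo = CohortTable(
            features={"mri1": small_cohort.features["mri1"]},
            initial_volume_mm3=small_cohort.initial_volume_mm3,
            followup_volume_mm3=small_cohort.followup_volume_mm3,
        )
        with pytest.raises(ValueError, match="delta"):
            build_series_matrix(solo, SeriesSpec(mode="delta", series="A"))


class TestComputeMetrics:
    def test_hand_computed_confusion(self):
        m = compute_metrics(tp=2, fn=0, tn=1, fp=1)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.5
        assert m["accuracy"] == 0.75
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(0.8)

    def test_perfect_and_degenerate_predictions(self):
        perfect = compute_metrics(tp=3, fn=0, tn=5, fp=0)
        assert all(perfect[k] == 1.0 for k in ("sensitivity", "specificity", "accuracy", "precision", "f1"))
        none_pred = compute_metrics(tp=0, fn=3, tn=5, fp=0)
        assert none_pred["precision"] == 0.0
        assert none_pred["precision_undefined"] == 1.0
        assert none_pred["f1"] == 0.0


class TestSelection:
    def test_selects_requested_count_and_subset(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="E"))
        res = rfe_frequency_select(X, y, n_select=9, iters=3, seed=0)
        assert len(res.selected) == 9
        assert set(res.selected) <= set(X.columns)

    def test_planted_features_dominate_frequency(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="E"))
        res = rfe_frequency_select(X, y, n_select=9, iters=5, seed=0)
        for name in ("core_GM_mean", "oct_RAS_RG_mean"):
            assert name in res.selected
            assert res.frequency[name] == 5

    def test_determinism_and_seed_sensitivity(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="D"))
        a = rfe_frequency_select(X, y, iters=3, seed=4)
        b = rfe_frequency_select(X, y, iters=3, seed=4)
        assert a.selected == b.selected
        assert a.frequency == b.frequency

    def test_single_class_labels_rejected(self, small_cohort):
        X, _ = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="A"))
        with pytest.raises(StratificationError):
            rfe_frequency_select(X, np.ones(len(X), dtype=int), iters=2)

    def test_pool_smaller_than_target_rejected(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="A"))
        with pytest.raises(ValueError):
            rfe_frequency_select(X[["core_GM_mean"]], y, n_select=9)


class TestCrossValidate:
    def test_stratified_fold_ratios(self):
        """Each fold's class ratio deviates from the cohort's by <= 1 sample."""
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 14 + [0] * 55)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        expected_pos = 14 / 5
        for _, te in skf.split(np.zeros((69, 1)), y):
            assert abs(y[te].sum() - expected_pos) <= 1

    def test_separable_feature_scores_perfectly(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 20)
        X = pd.DataFrame({"f": y * 10.0 + rng.normal(0, 0.1, 40)})
        cv = cross_validate(X, y, folds=5, iters=3, seed=0)
        assert cv.mean("auc") == 1.0
        assert cv.mean("f1") == 1.0

    def test_determinism(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="A"))
        a = cross_validate(X, y, folds=5, iters=4, seed=9)
        b = cross_validate(X, y, folds=5, iters=4, seed=9)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        pd.testing.assert_frame_equal(a.fold_scores, b.fold_scores)

    def test_metric_summaries_are_bounded(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="B"))
        cv = cross_validate(X, y, folds=5, iters=3, seed=1)
        s = cv.summary
        assert ((s["mean"] >= 0) & (s["mean"] <= 1)).all()
        assert (s["ci_low"] <= s["ci_high"]).all()
        assert ((s["ci_low"] >= 0) & (s["ci_high"] <= 1)).all()

    def test_minority_smaller_than_folds_rejected(self):
        y = np.array([1] * 3 + [0] * 30)
        X = pd.DataFrame({"f": np.arange(33, dtype=float)})
        with pytest.raises(StratificationError):
            cross_validate(X, y, folds=5, iters=2)


class TestModelEnumeration:
    def test_two_timepoint_cohort_yields_15_models(self, small_cohort):
        reports = run_all_individual_models(small_cohort, folds=5, iters=2, seed=0)
        assert tuple(reports) == MODEL_NAMES
        assert len(reports) == 15
        for name, rep in reports.items():
            assert len(rep.features) == 9
            if name[1] in "DE":
                assert rep.selection is not None

    def test_single_timepoint_cohort_degrades_to_5(self, small_cohort):
        solo = CohortTable(
            features={"mri1": small_cohort.features["mri1"]},
            initial_volume_mm3=small_cohort.initial_volume_mm3,
            followup_volume_mm3=small_cohort.followup_volume_mm3,
        )
        with pytest.warns(UserWarning, match="5 of the 15"):
            reports = run_all_individual_models(solo, folds=5, iters=2, seed=0)
        assert sorted(reports) == ["1A", "1B", "1C", "1D", "1E"]

    def test_same_seed_reproduces_reports(self, small_cohort):
        r1 = run_all_individual_models(small_cohort, folds=5, iters=2, seed=3)
        r2 = run_all_individual_models(small_cohort, folds=5, iters=2, seed=3)
        for name in r1:
            assert r1[name].features == r2[name].features
            pd.testing.assert_frame_equal(r1[name].metrics.summary, r2[name].metrics.summary)


class TestEfsModel:
    def test_pool_union_and_final_count(self, small_cohort):
        selection, metrics, coef = efs_model(small_cohort, seed=0, iters=2)
        assert len(selection.selected) == 9
        assert 9 <= len(selection.frequency) <= 27
        assert len(coef) == 9
        modes = {name.split(":")[0] for name in selection.frequency}
        assert modes <= {"mri1", "mri2", "delta"}

    def test_signal_concentrated_in_one_mode_wins(self):
        cohort = make_feature_cohort(CohortSpec(
            n_lesions=60, class_balance=0.5, seed=17,
            planted_features={f"mri1:oct_RAS_{p}_mean": 3.0 for p in ("GM", "RG", "RD")}))
        selection, _, _ = efs_model(cohort, seed=0, iters=5)
        planted = {"mri1:oct_RAS_GM_mean", "mri1:oct_RAS_RG_mean", "mri1:oct_RAS_RD_mean"}
        assert planted <= set(selection.selected)

    def test_positive_coefficients_point_to_non_responders(self, small_cohort):
        selection, _, coef = efs_model(small_cohort, seed=0, iters=2)
        # the planted features elevate non-responders, so their refit
        # coefficients must be positive under the stated polarity
        for name in ("mri1:core_GM_mean", "mri1:oct_RAS_RG_mean"):
            if name in coef.index:
                assert coef[name] > 0

    def test_requires_both_timepoints(self, small_cohort):
        solo = CohortTable(
            features={"mri1": small_cohort.features["mri1"]},
            initial_volume_mm3=small_cohort.initial_volume_mm3,
            followup_volume_mm3=small_cohort.followup_volume_mm3,
        )
        with pytest.raises(ValueError, match="timepoint"):
            efs_model(solo, seed=0, iters=2)


class TestFeatureReports:
    def test_self_correlation_and_monotone_invariance(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="E"))
        X = X.copy()
        X["monotone_twin"] = np.exp(X["core_GM_mean"])
        rep = report_feature_stats(X, y, ["core_GM_mean", "monotone_twin", "margin_RD_std"])
        sp = rep["spearman"]
        assert sp.loc["core_GM_mean", "core_GM_mean"] == pytest.approx(1.0)
        assert sp.loc["core_GM_mean", "monotone_twin"] == pytest.approx(1.0)

    def test_planted_feature_is_significant(self, small_cohort):
        X, y = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="E"))
        rep = report_feature_stats(X, y, ["core_GM_mean", "margin_GM_cv"])
        tests = rep["group_tests"]
        assert tests.loc["core_GM_mean", "p_value"] < 1e-4
        assert tests.loc["margin_GM_cv", "p_value"] > 0.01
        assert set(tests["test"]) <= {"t-test", "mannwhitneyu"}
        assert "p_bh" in tests.columns

    def test_null_p_values_are_uniform(self):
        """With permuted labels the two-group p-values follow U(0,1)."""
        from scipy import stats as sps

        rng = np.random.default_rng(23)
        n = 200
        X = pd.DataFrame(rng.standard_normal((n, 40)),
                         columns=[f"f{i}" for i in range(40)])
        y = np.array([0, 1] * (n // 2))
        rep = report_feature_stats(X, y, list(X.columns))
        ks = sps.kstest(rep["group_tests"]["p_value"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_tiny_group_rejected(self, small_cohort):
        X, _ = build_series_matrix(small_cohort, SeriesSpec(mode="mri1", series="A"))
        y = np.array([1] * 2 + [0] * 38)
        with pytest.raises(ValueError, match="3 samples"):
            report_feature_stats(X, y, ["core_GM_mean"])
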