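"""Metrics, bootstrap intervals, threshold sweeps, importance tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from manavoc.evaluate import (
    aggregate_importance,
    confusion_metrics,
    regression_metrics,
    subject_bootstrap_ci,
    threshold_sweep,
    within_subject_bootstrap,
)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics(["F", "M", "F"], ["F", "M", "F"])
        assert m.accuracy == 1.0 and m.macro_f1 == 1.0

    def test_hand_computed_confusion_table(self):
        m = confusion_metrics(list("FFFM"), list("FFMM"))
        assert m.accuracy == 0.75
        f, mm = m.per_class["F"], m.per_class["M"]
        assert f["precision"] == 1.0
        assert f["recall"] == pytest.approx(2 / 3)
        assert f["f1"] == pytest.approx(0.8)
        assert mm["precision"] == 0.5
        assert mm["recall"] == 1.0
        assert mm["f1"] == pytest.approx(2 / 3)
        assert m.macro_f1 == pytest.approx((0.8 + 2 / 3) / 2)

    def test_one_class_predictor_on_balanced_data(self):
        m = confusion_metrics(["a", "a", "b", "b"], ["a", "a", "a", "a"])
        assert m.accuracy == 0.5
        assert m.macro_f1 == pytest.approx((2 / 3 + 0.0) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 2], [1])


class TestSubjectBootstrap:
    def test_degenerate_all_perfect(self):
        ci = subject_bootstrap_ci({"a": 1.0, "b": 1.0, "c": 1.0}, seed=0)
        assert (ci.lower_95, ci.upper_95) == (1.0, 1.0)
        assert ci.sd == 0.0

    def test_two_subject_enumerable_distribution(self):
        # resample distribution of the mean is {0, .5, 1} w.p. {1/4, 1/2, 1/4}
        ci = subject_bootstrap_ci({"a": 0.0, "b": 1.0}, n_iter=10_000, seed=1)
        assert ci.lower_95 == 0.0 and ci.upper_95 == 1.0
        assert ci.mean == pytest.approx(0.5, abs=0.02)
        assert ci.sd == pytest.approx(np.sqrt(0.125), abs=0.02)

    def test_deterministic_under_seed(self):
        accs = {f"s{i}": a for i, a in enumerate([0.9, 0.8, 0.7, 1.0, 0.6])}
        a = subject_bootstrap_ci(accs, seed=7)
        b = subject_bootstrap_ci(accs, seed=7)
        assert (a.lower_95, a.upper_95, a.mean, a.sd) == (
            b.lower_95, b.upper_95, b.mean, b.sd,
        )

    def test_width_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (10, 40, 160):
            accs = {str(i): float(np.clip(rng.normal(0.8, 0.1), 0, 1)) for i in range(n)}
            ci = subject_bootstrap_ci(accs, n_iter=4000, seed=3)
            widths.append(ci.upper_95 - ci.lower_95)
        assert widths[0] > widths[1] > widths[2]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            subject_bootstrap_ci({"a": 0.5})


class TestWithinSubjectBootstrap:
    def test_all_correct_degenerate(self):
        ci = within_subject_bootstrap([1] * 12, seed=0)
        assert (ci.lower_95, ci.upper_95) == (1.0, 1.0)

    def test_18_of_27_lower_bound_matches_binomial_quantile(self):
        # bootstrap proportion ~ Binomial(27, 2/3)/27; 2.5th percentile = 13
        ci = within_subject_bootstrap([1] * 18 + [0] * 9, n_iter=10_000, seed=0)
        assert ci.lower_95 == pytest.approx(13 / 27, abs=1e-9)

    def test_single_call_degenerate(self):
        ci = within_subject_bootstrap([1], seed=0)
        assert ci.lower_95 == ci.upper_95 == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            within_subject_bootstrap([])


class TestThresholdSweep:
    def test_direct_counts_at_half(self):
        curve = threshold_sweep(
            [0.2, 0.6, 0.9], ["neg", "pos", "pos"], "pos", grid=np.array([0.5])
        )
        assert curve.minority_recall[0] == 1.0
        assert curve.fpr[0] == 0.0

    def test_extreme_threshold_kills_recall(self):
        curve = threshold_sweep(
            [0.2, 0.6, 0.9], ["neg", "pos", "pos"], "pos", grid=np.array([0.95])
        )
        assert curve.minority_recall[0] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=100)
    def test_recall_and_fpr_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        prob = rng.random(n)
        y = np.where(rng.random(n) < 0.3, "pos", "neg")
        if not (y == "pos").any() or not (y == "neg").any():
            return
        curve = threshold_sweep(prob, y, "pos")
        assert np.all(np.diff(curve.minority_recall) <= 1e-12)
        assert np.all(np.diff(curve.fpr) <= 1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([0.5], ["pos"], "pos", grid=np.array([0.0, 0.5]))


class TestAggregateImportance:
    def test_single_fold_passthrough_normalized(self):
        table = aggregate_importance([{"a": 0.5, "b": 0.3, "c": 0.2}])
        assert table["importance"].sum() == pytest.approx(1.0)
        assert list(table["feature"]) == ["a", "b", "c"]

    def test_two_fold_average(self):
        table = aggregate_importance([{"a": 1.0, "b": 0.0}, {"a": 0.0, "b": 1.0}])
        assert np.allclose(table["importance"], [0.5, 0.5])
        assert list(table["feature"]) == ["a", "b"]  # name tie-break

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_importance([])


class TestRegressionMetrics:
    def test_hand_computed_example(self):
        rep = regression_metrics([2.0, 3.0], [2.5, 2.5], ["a", "b"])
        assert rep.mae == pytest.approx(0.5)
        assert rep.rmse == pytest.approx(0.5)
        assert rep.r2 == pytest.approx(0.0)

    def test_perfect_predictions(self):
        rep = regression_metrics([2.0, 2.5, 3.0], [2.0, 2.5, 3.0], list("abc"))
        assert rep.mae == 0.0 and rep.r2 == 1.0

    def test_constant_mean_prediction_zero_r2(self):
        y = np.array([2.0, 2.4, 2.8])
        rep = regression_metrics(y, np.full(3, y.mean()), list("abc"))
        assert rep.r2 == pytest.approx(0.0)
        assert rep.rmse >= rep.mae >= 0

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([2.0, 2.0], [2.1, 2.2], ["a", "b"])
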