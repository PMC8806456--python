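"""Metric panel closed forms, ROC/AUC dual formulas and the search harnesses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmcnet as F
from fmcnet.evaluation import (DEFAULT_WIDTHS, EvaluationError, run_ablation,
                               width_search)


class TestConfusion:
    def test_perfect_case(self):
        c = F.confusion(np.array([0.9, 0.1]), np.array([1, 0]))
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_threshold_boundary_calls_positive(self):
        c = F.confusion(np.array([0.5, 0.5]), np.array([1, 0]), threshold=0.5)
        assert (c.tp, c.fp) == (1, 1) and (c.tn, c.fn) == (0, 0)

    def test_single_class_labels(self):
        c = F.confusion(np.array([0.8, 0.2]), np.array([1, 1]))
        assert c.tn == 0 and c.fp == 0

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            F.confusion(np.array([]), np.array([]))


class TestMetricPanel:
    def test_symmetric_counts(self):
        r = F.metric_panel(F.ConfusionCounts(tp=87, fp=13, tn=87, fn=13))
        assert r.sensitivity == r.specificity == r.ppv == r.npv == 0.87
        assert r.accuracy == 0.87

    def test_corner_case(self):
        r = F.metric_panel(F.ConfusionCounts(tp=1, fn=0, tn=0, fp=1))
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_zero_denominator_reported_undefined(self):
        r = F.metric_panel(F.ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert r.ppv is None and "ppv" in r.undefined
        assert r.npv == 0.5

    def test_matches_closed_forms_and_weighted_mean_identity(self):
        """accuracy must lie between sensitivity and specificity — it is their
        prevalence-weighted mean for any single confusion matrix."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 100, 4)
            c = F.ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            r = F.metric_panel(c)
            assert r.sensitivity == pytest.approx(tp / (tp + fn))
            assert r.specificity == pytest.approx(tn / (tn + fp))
            assert r.ppv == pytest.approx(tp / (tp + fp))
            assert r.npv == pytest.approx(tn / (tn + fn))
            assert r.accuracy == pytest.approx((tp + tn) / c.n)
            lo, hi = sorted([r.sensitivity, r.specificity])
            assert lo - 1e-12 <= r.accuracy <= hi + 1e-12


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
def test_accuracy_between_sensitivity_and_specificity(counts):
    tp, fp, tn, fn = counts
    r = F.metric_panel(F.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    lo, hi = sorted([r.sensitivity, r.specificity])
    assert lo - 1e-12 <= r.accuracy <= hi + 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        curve, auc = F.roc_auc(scores, labels)
        assert auc == 1.0
        assert curve.fpr[0] == 0 and curve.tpr[-1] == 1

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=300)
        labels = rng.integers(0, 2, 300)
        curve, _ = F.roc_auc(scores, labels)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=2000)
        labels = rng.permutation([0, 1] * 1000)
        _, auc = F.roc_auc(scores, labels)
        assert 0.45 < auc < 0.55

    def test_trapezoid_equals_rank_statistic_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = np.round(rng.uniform(size=200), 1)  # heavy ties
            labels = rng.integers(0, 2, 200)
            if len(np.unique(labels)) < 2:
                continue
            _, auc = F.roc_auc(scores, labels)
            assert abs(auc - F.rank_auc(scores, labels)) <= 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            F.roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestWidthSearch:
    def test_default_candidate_list_is_powers_of_two_32_to_4096(self):
        assert DEFAULT_WIDTHS == (32, 64, 128, 256, 512, 1024, 2048, 4096)
        assert len(DEFAULT_WIDTHS) == 8
        assert all(b == 2 * a for a, b in zip(DEFAULT_WIDTHS, DEFAULT_WIDTHS[1:]))

    def test_argmax_with_smallest_width_tiebreak(self):
        oracle = {32: 0.7, 64: 0.9, 128: 0.9}
        result = width_search([32, 64, 128], trainer=lambda w: oracle[w])
        assert result.selected_width == 64
        assert result.accuracies == [0.7, 0.9, 0.9]

    def test_failed_width_excluded_with_record(self):
        def trainer(w):
            if w == 64:
                raise RuntimeError("boom")
            return {32: 0.6, 128: 0.8}[w]

        result = width_search([32, 64, 128], trainer=trainer)
        assert result.widths == [32, 128]
        assert result.selected_width == 128
        assert 64 in result.failures

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            width_search([], trainer=lambda w: 0.5)

    def test_injected_trainer_deterministic(self):
        calls = []
        result = width_search([8, 16], trainer=lambda w: calls.append(w) or 0.5)
        assert calls == [8, 16]
        assert result.selected_width == 8


@pytest.fixture(scope="module")
def micro():
    cfg = F.SyntheticConfig(n_samples=24, seed=21)
    images, labels, _, _ = F.generate_arrays(cfg)
    from .conftest import make_split_tensors
    splits, _ = make_split_tensors(images, labels, seed=21)
    return splits


class TestRunAblation:

    def test_six_variant_table(self, micro):
        tc = F.from_scratch_config(seed=0, epochs=1, batch_size=8)
        table = run_ablation(["A", "B", "C", "D", "E", "FMC"], micro, tc,
                             base_spec=F.ArchitectureSpec(size_profile="tiny"))
        assert len(table) == 6
        assert list(table["variant"]) == ["A", "B", "C", "D", "E", "FMC"]
        assert set(table.columns) >= {"variant", "accuracy", "sensitivity",
                                      "specificity", "ppv", "npv", "auc"}

    def test_repeat_identical(self, micro):
        tc = F.from_scratch_config(seed=3, epochs=1, batch_size=8)
        t1 = run_ablation(["A", "FMC"], micro, tc,
                          base_spec=F.ArchitectureSpec(size_profile="tiny"), seed=3)
        t2 = run_ablation(["A", "FMC"], micro, tc,
                          base_spec=F.ArchitectureSpec(size_profile="tiny"), seed=3)
        assert t1.equals(t2)


def test_evaluate_model_full_panel(trained_tiny):
    x, y = trained_tiny["splits"]["test"]
    report = F.evaluate_model(trained_tiny["model"], x, y)
    assert report.auc is not None and report.auc > 0.8
    assert report.accuracy is not None and 0 <= report.accuracy <= 1
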