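"""Threshold selection, metric arithmetic, AUROC/AUPRC oracles and the
stratified bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from pcct_ews.evaluation import (
    auprc,
    auroc,
    bootstrap_ci,
    compute_metrics,
    evaluate,
    select_threshold,
)


def brute_force_auroc(scores, labels):
    """O(n^2) pair-ordering oracle; ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_matches_pair_ordering_oracle():
    rng = np.random.default_rng(0)
    scores = np.round(rng.random(200), 2)  # rounding forces ties
    labels = rng.integers(0, 2, 200)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))


def test_auroc_agrees_with_sklearn_cross_check():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=300)
    labels = (scores + rng.normal(size=300) > 0).astype(int)
    assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


def test_all_tied_scores_give_auroc_half():
    assert auroc(np.ones(10), np.array([0, 1] * 5)) == pytest.approx(0.5)


@given(
    st.lists(st.floats(min_value=-5, max_value=5), min_size=6, max_size=40),
    st.floats(min_value=0.1, max_value=3.0),
    st.floats(min_value=0.1, max_value=1.0),
)
@settings(max_examples=40, deadline=None)
def test_auroc_invariant_under_monotone_transforms(vals, a, b):
    # scores on a coarse grid so the exponential cannot collapse distinct
    # values into new floating-point ties
    scores = np.round(np.asarray(vals), 2)
    labels = (np.arange(len(scores)) % 2).astype(int)
    transformed = np.exp(b * scores) * a
    assert auroc(scores, labels) == pytest.approx(auroc(transformed, labels))


def test_auprc_agrees_with_sklearn_step_integration():
    rng = np.random.default_rng(2)
    scores = np.round(rng.random(250), 2)
    labels = (rng.random(250) < 0.15).astype(int)
    labels[0] = 1
    assert auprc(scores, labels) == pytest.approx(
        average_precision_score(labels, scores)
    )


def test_select_threshold_on_enumerated_example():
    """Negatives {0.1, 0.2, 0.3, 0.9}, positives {0.8, 0.95}: a 20 % FPR cap
    admits zero false positives, so the cut lands above 0.9 and catches one of
    the two positives."""
    scores = np.array([0.1, 0.2, 0.3, 0.9, 0.8, 0.95])
    labels = np.array([0, 0, 0, 0, 1, 1])
    t = select_threshold(scores, labels, max_fpr=0.20)
    assert 0.9 < t <= 0.95
    assert np.mean(scores[labels == 1] >= t) == 0.5  # sensitivity 1/2
    assert np.mean(scores[labels == 0] >= t) == 0.0


def test_select_threshold_brute_force_most_sensitive_under_cap():
    rng = np.random.default_rng(3)
    scores = np.round(rng.random(120), 2)
    labels = (rng.random(120) < 0.3).astype(int)
    labels[:2] = [0, 1]
    t = select_threshold(scores, labels, max_fpr=0.20)
    neg, pos = scores[labels == 0], scores[labels == 1]
    assert np.mean(neg >= t) <= 0.20
    # no lower candidate satisfies the cap with higher sensitivity
    for c in np.unique(scores):
        if c < t:
            assert np.mean(neg >= c) > 0.20


def test_perfect_separation_gives_full_sensitivity_at_zero_fpr():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    t = select_threshold(scores, labels)
    assert np.mean(scores[labels == 1] >= t) == 1.0
    assert np.mean(scores[labels == 0] >= t) == 0.0


def test_tuning_specificity_always_at_least_eighty_percent():
    rng = np.random.default_rng(4)
    for trial in range(20):
        scores = rng.random(80)
        labels = (rng.random(80) < 0.25).astype(int)
        if labels.min() == labels.max():
            continue
        t = select_threshold(scores, labels, max_fpr=0.20)
        spec = np.mean(scores[labels == 0] < t)
        assert spec >= 0.80


def test_degenerate_scores_warn_and_return_above_max():
    scores = np.full(10, 0.7)
    labels = np.array([0, 1] * 5)
    with pytest.warns(UserWarning, match="FPR cap"):
        t = select_threshold(scores, labels, max_fpr=0.2)
    assert t > 0.7


def test_confusion_metric_arithmetic():
    """TP=3 FN=1 TN=8 FP=2 at threshold 0.5."""
    scores = np.array([0.9] * 3 + [0.1] + [0.2] * 8 + [0.8] * 2)
    labels = np.array([1] * 3 + [1] + [0] * 8 + [0] * 2)
    r = compute_metrics(scores, labels, 0.5)
    m = r.metrics
    assert m["sensitivity"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(0.8)
    assert m["ppv"] == pytest.approx(0.6)
    assert m["npv"] == pytest.approx(8 / 9)
    assert m["balanced_accuracy"] == pytest.approx(0.775)
    assert m["f1"] == pytest.approx(2 * 0.6 * 0.75 / (0.6 + 0.75))
    assert (r.n_pos, r.n_neg) == (4, 10)


def test_single_class_labels_raise():
    with pytest.raises(ValueError, match="both classes"):
        compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]), 0.5)


def test_bootstrap_single_iteration_collapses_ci():
    scores = np.array([0.1, 0.9, 0.2, 0.8, 0.3, 0.7])
    labels = np.array([0, 1, 0, 1, 0, 1])
    ci, _ = bootstrap_ci(scores, labels, 0.5, iterations=1, seed=0)
    for lo, hi in ci.values():
        assert lo == hi or (np.isnan(lo) and np.isnan(hi))


def test_bootstrap_is_seeded_and_preserves_class_counts():
    rng = np.random.default_rng(5)
    scores = rng.random(60)
    labels = (rng.random(60) < 0.3).astype(int)
    labels[:2] = [0, 1]
    a, _ = bootstrap_ci(scores, labels, 0.5, iterations=200, seed=9)
    b, _ = bootstrap_ci(scores, labels, 0.5, iterations=200, seed=9)
    assert a == b


def test_point_metric_inside_its_bootstrap_ci():
    rng = np.random.default_rng(6)
    scores = rng.random(200)
    labels = (scores + rng.normal(0, 0.5, 200) > 0.6).astype(int)
    t = select_threshold(scores, labels)
    report = evaluate(scores, labels, t, iterations=500, seed=0)
    for m in ("auroc", "sensitivity", "specificity"):
        lo, hi = report.ci[m]
        assert lo <= report.metrics[m] <= hi
        assert lo <= hi


def test_ci_width_shrinks_with_sample_size():
    rng = np.random.default_rng(7)

    def width(n):
        scores = rng.random(n)
        labels = (scores + rng.normal(0, 0.6, n) > 0.5).astype(int)
        ci, _ = bootstrap_ci(scores, labels, 0.5, iterations=300, seed=1)
        lo, hi = ci["auroc"]
        return hi - lo

    w_small = np.mean([width(100) for _ in range(5)])
    w_large = np.mean([width(1000) for _ in range(5)])
    assert w_large < w_small


def test_undefined_replicate_metrics_are_excluded_and_counted():
    # threshold above every score: zero predicted positives -> PPV undefined
    scores = np.array([0.1, 0.2, 0.3, 0.4])
    labels = np.array([0, 1, 0, 1])
    ci, excl = bootstrap_ci(scores, labels, 0.99, iterations=50, seed=0)
    assert excl["ppv"] == 50
    assert np.isnan(ci["ppv"][0])
    assert excl["auroc"] == 0


def test_label_permutation_auroc_centres_on_half():
    """Leakage canary: shuffling labels against fixed scores must destroy
    discrimination."""
    rng = np.random.default_rng(8)
    scores = rng.random(300)
    labels = (scores > 0.7).astype(int)
    aucs = []
    for _ in range(100):
        perm = rng.permutation(labels)
        if perm.min() != perm.max():
            aucs.append(auroc(scores, perm))
    assert abs(np.mean(aucs) - 0.5) < 0.02
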