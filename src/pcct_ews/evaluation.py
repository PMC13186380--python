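"""Threshold selection, discrimination and threshold-dependent metrics, and
stratified bootstrap confidence intervals.

The operating point is chosen on the tuning set as the most sensitive
threshold whose false positive rate stays at or below a cap (default 20 %,
i.e. specificity >= 80 %), then frozen for test evaluation. A prediction is
positive iff score >= threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

THRESHOLD_METRICS = (
    "sensitivity", "specificity", "ppv", "npv", "balanced_accuracy", "f1",
)
ALL_METRICS = ("auroc", "auprc") + THRESHOLD_METRICS


def _check_two_class(labels: np.ndarray):
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels.astype(int)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the rank (Mann-Whitney) identity; ties get mid-ranks."""
    labels = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration
    (sum over threshold steps of delta-recall times precision; no trapezoid)."""
    labels = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied score block
    last = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    tp, fp = tp[last], fp[last]
    n_pos = int(labels.sum())
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def select_threshold(
    tune_scores: np.ndarray, tune_labels: np.ndarray, max_fpr: float = 0.20
) -> float:
    """Most sensitive threshold whose tuning-set FPR is <= ``max_fpr``.

    Candidates are the unique observed scores plus a sentinel above the
    maximum; the smallest candidate satisfying the cap is returned (smaller
    thresholds admit more predicted positives, hence higher sensitivity).
    """
    labels = _check_two_class(tune_labels)
    scores = np.asarray(tune_scores, dtype=float)
    neg = scores[labels == 0]
    candidates = np.unique(scores)
    for t in candidates:
        fpr = np.mean(neg >= t)
        if fpr <= max_fpr:
            return float(t)
    eps = 1e-9 + 1e-9 * abs(scores.max())
    warnings.warn(
        "no observed score satisfies the FPR cap; returning max score + eps"
    )
    return float(scores.max() + eps)


def _confusion_metrics(scores, labels, threshold) -> dict[str, float]:
    pred = np.asarray(scores) >= threshold
    y = np.asarray(labels).astype(bool)
    tp = float(np.sum(pred & y))
    fp = float(np.sum(pred & ~y))
    fn = float(np.sum(~pred & y))
    tn = float(np.sum(~pred & ~y))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    bal = (sens + spec) / 2
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) and np.isfinite(ppv + sens) and (ppv + sens) > 0 else np.nan
    return {
        "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
        "balanced_accuracy": bal, "f1": f1,
    }


@dataclass
class MetricsReport:
    """Point metrics with 95 % bootstrap CIs at a frozen threshold."""

    threshold: float
    n_pos: int
    n_neg: int
    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_iterations: int = 0
    bootstrap_exclusions: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def as_dict(self) -> dict:
        out = {
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "bootstrap_iterations": self.bootstrap_iterations,
            "seed": self.seed,
            "metrics": {},
        }
        for m, v in self.metrics.items():
            lo, hi = self.ci.get(m, (None, None))
            out["metrics"][m] = {"point": v, "ci_low": lo, "ci_high": hi}
        return out


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> MetricsReport:
    """Point values of all discrimination and threshold-dependent metrics."""
    labels = _check_two_class(labels)
    m = {"auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}
    m.update(_confusion_metrics(scores, labels, threshold))
    return MetricsReport(
        threshold=float(threshold),
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
        metrics=m,
    )


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    iterations: int = 5000,
    seed: int = 0,
) -> tuple[dict[str, tuple[float, float]], dict[str, int]]:
    """Class-stratified bootstrap 95 % CIs at the frozen threshold.

    Each replicate resamples positives and negatives separately with
    replacement, preserving class counts. Replicates where a metric is
    undefined (e.g. PPV with zero predicted positives) are excluded from that
    metric's percentiles; exclusion counts are reported.
    """
    labels = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    reps = {m: np.empty(iterations) for m in ALL_METRICS}
    for b in range(iterations):
        idx = np.concatenate([
            rng.choice(pos_idx, size=len(pos_idx), replace=True),
            rng.choice(neg_idx, size=len(neg_idx), replace=True),
        ])
        s, y = scores[idx], labels[idx]
        reps["auroc"][b] = auroc(s, y)
        reps["auprc"][b] = auprc(s, y)
        for m, v in _confusion_metrics(s, y, threshold).items():
            reps[m][b] = v
    ci: dict[str, tuple[float, float]] = {}
    exclusions: dict[str, int] = {}
    for m, arr in reps.items():
        ok = arr[np.isfinite(arr)]
        exclusions[m] = int(iterations - len(ok))
        if len(ok) == 0:
            ci[m] = (np.nan, np.nan)
        else:
            ci[m] = (
                float(np.percentile(ok, 2.5)),
                float(np.percentile(ok, 97.5)),
            )
    return ci, exclusions


def evaluate(
    test_scores: np.ndarray,
    test_labels: np.ndarray,
    threshold: float,
    iterations: int = 5000,
    seed: int = 0,
) -> MetricsReport:
    """Full report on a held-out set at a frozen threshold."""
    report = compute_metrics(test_scores, test_labels, threshold)
    ci, excl = bootstrap_ci(test_scores, test_labels, threshold, iterations, seed)
    report.ci = ci
    report.bootstrap_iterations = iterations
    report.bootstrap_exclusions = excl
    report.seed = seed
    return report
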