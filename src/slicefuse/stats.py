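"""Confusion-matrix metrics, ROC/AUC, and the paired DeLong test.

The positive class is appendicitis (the canonical ``positive`` label): TP is
appendicitis classified as appendicitis, FN appendicitis classified as
diverticulitis, FP diverticulitis classified as appendicitis, TN
diverticulitis classified as diverticulitis. Per-fold test confusion
matrices are pooled (elementwise sum) into a whole-dataset matrix before
metrics are computed, so every image contributes exactly once.

Also provides an integer reconstruction oracle: given the class totals and a
report's printed precision and recall (2 decimal places), exhaustively
recover every confusion matrix consistent with them — a consistency check on
published results tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "MetricValue",
    "MetricReport",
    "RocResult",
    "DeLongComparison",
    "confusion_from_scores",
    "pool_confusions",
    "metrics_from_confusion",
    "auc_mann_whitney",
    "roc_result",
    "delong_components",
    "delong_paired_test",
    "reconstruct_confusion_from_printed",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive class = appendicitis)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricValue:
    """A percentage with its 95% confidence interval; undefined when the
    denominator is zero."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class MetricReport:
    accuracy: MetricValue
    precision: MetricValue
    recall: MetricValue


@dataclass(frozen=True)
class RocResult:
    """Scores with their ROC curve, Mann-Whitney AUC and DeLong variance."""

    labels: np.ndarray
    scores: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    delong_variance: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    variance_delta: float
    z: float
    p_value: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    degenerate: bool = False


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels


def confusion_from_scores(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """Threshold scores (positive iff score >= threshold) and count outcomes."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        fn=int(np.sum(~pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def pool_confusions(per_fold: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum of per-fold confusion matrices (whole-dataset matrix)."""
    if not per_fold:
        raise ValueError("need at least one confusion matrix")
    total = per_fold[0]
    for cm in per_fold[1:]:
        total = total + cm
    return total


def _proportion_metric(count: int, nobs: int) -> MetricValue:
    if nobs == 0:
        return MetricValue(None)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return MetricValue(100.0 * count / nobs, 100.0 * float(lo), 100.0 * float(hi))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, precision and recall (percent) with Wilson 95% CIs.

    A metric whose denominator is zero is reported undefined, not fabricated.
    """
    return MetricReport(
        accuracy=_proportion_metric(cm.tp + cm.tn, cm.n),
        precision=_proportion_metric(cm.tp, cm.tp + cm.fp),
        recall=_proportion_metric(cm.tp, cm.tp + cm.fn),
    )


def _split_scores(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability: P(pos > neg) + 0.5 P(tie).

    Equals the trapezoidal area under the empirical ROC curve.
    """
    pos, neg = _split_scores(labels, scores)
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def delong_components(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (V10 per positive, V01 per negative) and AUC."""
    pos, neg = _split_scores(labels, scores)
    psi = np.where(
        pos[:, None] > neg[None, :], 1.0, np.where(pos[:, None] == neg[None, :], 0.5, 0.0)
    )
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def _auc_ci(auc: float, var: float) -> tuple[float, float]:
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_result(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    """ROC curve, Mann-Whitney AUC and DeLong variance for one score vector."""
    labels = _check_binary(np.asarray(labels))
    v10, v01, auc = delong_components(labels, scores)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return RocResult(
        labels=labels,
        scores=np.asarray(scores, dtype=float),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        delong_variance=float(var),
        ci95=_auc_ci(auc, var),
    )


def delong_paired_test(
    labels: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
) -> DeLongComparison:
    """DeLong's test for two correlated AUCs measured on the same cases.

    Uses the structural-components estimator for var(AUC_A), var(AUC_B) and
    cov(AUC_A, AUC_B); the AUC difference divided by its standard error is
    referred to the standard normal (two-sided).
    """
    v10_a, v01_a, auc_a = delong_components(labels, scores_a)
    v10_b, v01_b, auc_b = delong_components(labels, scores_b)
    m, n = len(v10_a), len(v01_a)

    def cov(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    s10 = np.array([[cov(v10_a, v10_a), cov(v10_a, v10_b)], [cov(v10_b, v10_a), cov(v10_b, v10_b)]])
    s01 = np.array([[cov(v01_a, v01_a), cov(v01_a, v01_b)], [cov(v01_b, v01_a), cov(v01_b, v01_b)]])
    s = s10 / m + s01 / n
    var_a, var_b = float(s[0, 0]), float(s[1, 1])
    var_delta = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    delta = auc_a - auc_b

    degenerate = False
    if var_delta <= 0:
        if delta == 0:
            z, p = 0.0, 1.0
        else:
            z, p = np.inf if delta > 0 else -np.inf, 0.0
            degenerate = True
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2 * norm.sf(abs(z)))
    return DeLongComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=delta,
        variance_delta=var_delta,
        z=float(z),
        p_value=float(p),
        ci95_a=_auc_ci(auc_a, var_a),
        ci95_b=_auc_ci(auc_b, var_b),
        degenerate=degenerate,
    )


def _round2(values: np.ndarray) -> np.ndarray:
    """Round to 2 dp, half away from zero (the convention of printed tables)."""
    return np.floor(np.abs(values) * 100.0 + 0.5) / 100.0 * np.sign(values)


def reconstruct_confusion_from_printed(
    n_pos: int, n_neg: int, recall_2dp: float, precision_2dp: float
) -> list[ConfusionMatrix]:
    """All integer confusion matrices consistent with printed 2-dp metrics.

    Searches every TP in [0, n_pos] whose recall 100*TP/n_pos rounds to
    ``recall_2dp`` and, for each, every FP in [0, n_neg] whose precision
    100*TP/(TP+FP) rounds to ``precision_2dp``. An empty result means the
    printed numbers are mutually inconsistent with the stated class totals.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class totals must be >= 1")
    tp = np.arange(n_pos + 1)
    recall = 100.0 * tp / n_pos
    tp_candidates = tp[np.abs(_round2(recall) - recall_2dp) < 1e-9]
    out = []
    fp = np.arange(n_neg + 1)
    for t in tp_candidates:
        t = int(t)
        if t == 0:
            precision = np.where(fp == 0, np.nan, 0.0)
        else:
            precision = 100.0 * t / (t + fp)
        ok = np.abs(_round2(np.nan_to_num(precision, nan=-1.0)) - precision_2dp) < 1e-9
        for f in fp[ok]:
            out.append(ConfusionMatrix(tp=t, fn=n_pos - t, fp=int(f), tn=n_neg - int(f)))
    return out
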