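"""Confusion-matrix metrics, ROC construction, and Youden-index thresholding.

Diagnostic accuracy of a mammography AI model is summarized per study: the
model emits a malignancy probability in [0, 1], the ground truth is a binary
"with pathology" / "without pathology" label (derived from BI-RADS categories
when only those are available), and a probability threshold turns scores into
binary calls.  The threshold rule is inclusive: a score equal to or above the
threshold is called "with pathology".

The ROC curve is built over the candidate thresholds that are actually
achievable under that rule — the distinct observed scores plus a sentinel
above the maximum — and the AUC is the trapezoidal integral over the curve,
which equals the Mann-Whitney concordance probability with tied pairs
credited 0.5.  The operating point is chosen by maximizing the Youden index
J = sensitivity + specificity - 1; ties are broken toward the smallest
threshold (the sensitivity-favoring choice in a screening context).

Metrics with a zero denominator (e.g. specificity when there are no
negatives) are explicitly ``None``, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ROCCurve",
    "binarize",
    "label_from_birads",
    "confusion",
    "metric_set",
    "roc",
    "auc",
    "youden_threshold",
    "reconstruct_confusion",
    "evaluate_scores",
    "round_half_away",
]

#: BI-RADS categories mapped to the binary pathology classes: 1-2 are
#: negative/benign, 3-5 increasingly suspicious, 6 biopsy-proven malignancy.
_BIRADS_POSITIVE = {3, 4, 5, 6}
_BIRADS_NEGATIVE = {1, 2}


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (so +2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` is banker's rounding; reported tables in this
    domain round halves away from zero.
    """
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for binary calls against binary truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy-family metrics plus AUC; ``None`` marks an undefined value."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    auc: float | None = None

    _SLOTS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in self._SLOTS}

    def rounded(self, decimals: int = 2) -> dict[str, float | None]:
        """Display form: values rounded half-away-from-zero; None stays None."""
        return {
            name: None if v is None else round_half_away(v, decimals)
            for name, v in self.as_dict().items()
        }


@dataclass(frozen=True)
class ROCCurve:
    """Operating points (fpr, tpr, threshold) sorted by non-decreasing fpr.

    The first point is (0, 0) at a sentinel threshold above every score;
    the last is (1, 1) at the minimum observed score (every study called
    positive under the >= rule).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        fpr, tpr = np.asarray(self.fpr), np.asarray(self.tpr)
        if not (len(fpr) == len(tpr) == len(self.thresholds)):
            raise ValueError("fpr, tpr and thresholds must have equal length")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC points must be monotone in fpr and tpr")
        if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
            raise ValueError("ROC curve must span (0,0) to (1,1)")

    def __len__(self) -> int:
        return len(self.fpr)

    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist(), self.thresholds.tolist()))


def _check_unit_interval(values: np.ndarray, what: str) -> None:
    if np.any(np.isnan(values)) or np.any(values < 0) or np.any(values > 1):
        raise ValueError(f"{what} must lie in [0, 1]")


def binarize(scores, threshold: float):
    """Binary pathology calls: score >= threshold is "with pathology".

    The comparison is inclusive on the threshold, so a study scoring exactly
    at the operating point is called positive.
    """
    scores = np.asarray(scores, dtype=float)
    _check_unit_interval(scores, "scores")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return scores >= threshold


def label_from_birads(birads):
    """Map a BI-RADS category to the binary pathology label.

    Categories 3-5 (suspicious) and 6 (biopsy-proven malignancy) are
    "with pathology" (1); 1-2 are "without pathology" (0); a missing
    category yields ``None``.
    """
    if birads is None or (isinstance(birads, float) and math.isnan(birads)):
        return None
    birads = int(birads)
    if birads in _BIRADS_POSITIVE:
        return 1
    if birads in _BIRADS_NEGATIVE:
        return 0
    raise ValueError(f"BI-RADS category must be 1-6, got {birads}")


def confusion(calls, labels) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from paired binary calls and truth labels."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have the same length")
    if calls.size == 0:
        raise ValueError("cannot tally an empty input")
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be binary with no undefined values")
    calls = calls.astype(bool)
    truth = labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(calls & truth)),
        tn=int(np.sum(~calls & ~truth)),
        fp=int(np.sum(calls & ~truth)),
        fn=int(np.sum(~calls & truth)),
    )


def metric_set(c: ConfusionCounts, auc_value: float | None = None) -> MetricSet:
    """Derive the accuracy-family metrics from confusion counts.

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = TP / (TP + 0.5 (FP + FN))

    A metric whose denominator is zero is ``None``.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    return MetricSet(
        accuracy=ratio(c.tp + c.tn, c.total),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        precision=ratio(c.tp, c.tp + c.fp),
        f1=ratio(c.tp, c.tp + 0.5 * (c.fp + c.fn)),
        auc=auc_value,
    )


def roc(scores, labels) -> ROCCurve:
    """Construct the empirical ROC curve under the inclusive threshold rule.

    One operating point per distinct observed score (thresholding at that
    score), plus the (0, 0) point at a sentinel threshold above the maximum.
    Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    _check_unit_interval(scores, "scores")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")

    # Sort scores descending; cumulative counts at each distinct-score
    # boundary give the operating point for thresholding at that score.
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = (labels[order] == 1).astype(int)
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # last index of each run of equal scores
    boundary = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]

    fpr = np.r_[0.0, fps[boundary] / n_neg]
    tpr = np.r_[0.0, tps[boundary] / n_pos]
    thresholds = np.r_[np.inf, s[boundary]]
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties credited 0.5 (Mann-Whitney correspondence).
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_threshold(curve: ROCCurve) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Among thresholds tied for the maximum J (to within floating-point noise)
    the smallest is returned, favoring sensitivity.
    """
    j = curve.tpr - curve.fpr
    j_max = float(np.max(j))
    ties = np.nonzero(j >= j_max - 1e-12)[0]
    threshold = float(np.min(curve.thresholds[ties]))
    return threshold, j_max


def reconstruct_confusion(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Recover confusion counts from reported sensitivity/specificity.

    Useful for auditing published metric tables: with the class sizes known,
    tp = round(sens * n_pos) and tn = round(spec * n_neg) (halves away from
    zero) determine the full confusion matrix.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class sizes must be non-negative")
    tp = int(round_half_away(sensitivity * n_pos))
    tn = int(round_half_away(specificity * n_neg))
    fn = n_pos - tp
    fp = n_neg - tn
    if fn < 0 or fp < 0:
        raise ValueError("rounded counts exceed the class sizes")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class ScoreEvaluation:
    """Full per-cohort evaluation: curve, operating point, and metrics."""

    curve: ROCCurve
    threshold: float
    youden_j: float
    counts: ConfusionCounts
    metrics: MetricSet


def evaluate_scores(scores, labels, threshold: float | None = None) -> ScoreEvaluation:
    """Evaluate study scores against truth labels end to end.

    Builds the ROC curve, selects the operating threshold by the Youden index
    unless one is given, and computes the metric set at that threshold with
    the trapezoidal AUC attached.
    """
    curve = roc(scores, labels)
    area = auc(curve)
    if threshold is None:
        threshold, j = youden_threshold(curve)
    else:
        j = math.nan
    calls = np.asarray(scores, dtype=float) >= threshold
    counts = confusion(calls, labels)
    return ScoreEvaluation(
        curve=curve,
        threshold=threshold,
        youden_j=j,
        counts=counts,
        metrics=metric_set(counts, auc_value=area),
    )
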