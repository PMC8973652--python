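"""Evaluation suite: staging agreement, detection quality and rater statistics.

Staging is a 3-class problem (stages I, II, III/IV), evaluated against the
reference labels with a confusion matrix and the usual one-vs-rest rates
(accuracy, precision, sensitivity, specificity, F1).  Lesion detection is
evaluated PASCAL-style: greedy IoU matching at a fixed threshold, precision /
sensitivity / F1 over all matches, and average precision as the area under
the precision-recall envelope.  Rater agreement uses the intraclass
correlation coefficient ICC(2,1) (two-way random effects, absolute agreement,
single rater) and Pearson's chi-square test compares diagnostic tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from .pbl_core import STAGE_ORDER, Stage


class LengthMismatch(ValueError):
    pass


class EmptyMatrix(ValueError):
    pass


class OneClassOnly(ValueError):
    pass


class ZeroMargin(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confusion matrix and classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Square count matrix: rows are reference classes, columns predictions."""

    counts: np.ndarray
    labels: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    reference: Sequence, predicted: Sequence, labels: Sequence | None = None
) -> ConfusionMatrix:
    """Tally (reference, predicted) pairs; default class order is I, II, III/IV."""
    if len(reference) != len(predicted):
        raise LengthMismatch(f"{len(reference)} reference vs {len(predicted)} predicted")
    if labels is None:
        labels = STAGE_ORDER
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, p in zip(reference, predicted):
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


@dataclass
class ClassMetrics:
    """One-vs-rest rates for a single class; None marks an undefined rate."""

    accuracy: float
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    undefined: list[str] = field(default_factory=list)


@dataclass
class ClassificationReport:
    per_class: dict
    overall: ClassMetrics
    average: str  # "macro" or "micro"


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float | None:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def classification_metrics(
    cm: ConfusionMatrix, average: str = "macro"
) -> ClassificationReport:
    """Per-class one-vs-rest metrics plus an overall summary.

    Overall accuracy is always trace/total.  The other overall rates are the
    unweighted (macro) mean over classes by default; ``average="micro"`` pools
    the one-vs-rest counts instead.  Zero-denominator rates are reported as
    None and listed in ``undefined`` rather than propagating NaN; macro means
    skip them.
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise EmptyMatrix("confusion matrix has no observations")
    if average not in ("macro", "micro"):
        raise ValueError(f"unknown average {average!r}")

    per_class: dict = {}
    pooled = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for i, lab in enumerate(cm.labels):
        tp = int(c[i, i])
        fn = int(c[i, :].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = total - tp - fn - fp
        undef: list[str] = []
        precision = _safe_div(tp, tp + fp, "precision", undef)
        sensitivity = _safe_div(tp, tp + fn, "sensitivity", undef)
        specificity = _safe_div(tn, tn + fp, "specificity", undef)
        if precision is None or sensitivity is None or (precision + sensitivity) == 0:
            undef.append("f1")
            f1 = None
        else:
            f1 = 2 * precision * sensitivity / (precision + sensitivity)
        per_class[lab] = ClassMetrics(
            accuracy=(tp + tn) / total,
            precision=precision,
            sensitivity=sensitivity,
            specificity=specificity,
            f1=f1,
            undefined=undef,
        )
        for k, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
            pooled[k] += v

    overall_acc = float(np.trace(c)) / total
    undef_all: list[str] = []
    if average == "macro":
        def _macro(attr: str) -> float | None:
            vals = [getattr(m, attr) for m in per_class.values() if getattr(m, attr) is not None]
            if not vals:
                undef_all.append(attr)
                return None
            return float(np.mean(vals))

        overall = ClassMetrics(
            accuracy=overall_acc,
            precision=_macro("precision"),
            sensitivity=_macro("sensitivity"),
            specificity=_macro("specificity"),
            f1=_macro("f1"),
            undefined=undef_all,
        )
    else:
        tp, fp, fn, tn = pooled["tp"], pooled["fp"], pooled["fn"], pooled["tn"]
        precision = _safe_div(tp, tp + fp, "precision", undef_all)
        sensitivity = _safe_div(tp, tp + fn, "sensitivity", undef_all)
        specificity = _safe_div(tn, tn + fp, "specificity", undef_all)
        f1 = (
            2 * precision * sensitivity / (precision + sensitivity)
            if precision and sensitivity
            else None
        )
        overall = ClassMetrics(overall_acc, precision, sensitivity, specificity, f1, undef_all)
    return ClassificationReport(per_class=per_class, overall=overall, average=average)


# ---------------------------------------------------------------------------
# Detection evaluation (IoU matching, AP)
# ---------------------------------------------------------------------------

def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two half-open [x0, y0, x1, y1] boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def match_detections(
    detections: Sequence[tuple[Hashable, Sequence[float], float]],
    ground_truths: Sequence[tuple[Hashable, Sequence[float]]],
    iou_threshold: float = 0.5,
) -> list[bool]:
    """Greedy highest-score-first matching of detections to ground truths.

    Each detection is ``(image_id, box, score)``; each ground truth
    ``(image_id, box)`` and is matchable at most once.  Returns, in
    score-descending detection order, whether each detection is a true
    positive (IoU >= threshold with an unmatched same-image truth).
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i][2])
    by_image: dict[Hashable, list[int]] = {}
    for gi, (img, _box) in enumerate(ground_truths):
        by_image.setdefault(img, []).append(gi)
    matched = set()
    flags: list[bool] = []
    for di in order:
        img, box, _score = detections[di]
        best_iou, best_gi = 0.0, -1
        for gi in by_image.get(img, []):
            if gi in matched:
                continue
            v = box_iou(box, ground_truths[gi][1])
            if v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi >= 0 and best_iou >= iou_threshold:
            matched.add(best_gi)
            flags.append(True)
        else:
            flags.append(False)
    return flags


def average_precision(
    detections: Sequence[tuple[Hashable, Sequence[float], float]],
    ground_truths: Sequence[tuple[Hashable, Sequence[float]]],
    iou_threshold: float = 0.5,
) -> float | None:
    """AP for one class: area under the all-points precision-recall envelope.

    Returns None (undefined) when there is no ground truth of the class.
    """
    n_gt = len(ground_truths)
    if n_gt == 0:
        return None
    if not detections:
        return 0.0
    flags = match_detections(detections, ground_truths, iou_threshold)
    tp = np.cumsum(np.asarray(flags, dtype=np.float64))
    fp = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


@dataclass
class DetectionEvalResult:
    """Per-class detection scores at a fixed IoU threshold."""

    precision: float | None
    sensitivity: float | None
    f1: float | None
    ap: float | None


def detection_metrics(
    detections: Sequence[tuple[Hashable, Sequence[float], float]],
    ground_truths: Sequence[tuple[Hashable, Sequence[float]]],
    iou_threshold: float = 0.5,
) -> DetectionEvalResult:
    """Precision / sensitivity / F1 over all supplied detections, plus AP."""
    n_gt = len(ground_truths)
    ap = average_precision(detections, ground_truths, iou_threshold)
    if not detections:
        return DetectionEvalResult(None, 0.0 if n_gt else None, None, ap)
    flags = match_detections(detections, ground_truths, iou_threshold)
    tp = sum(flags)
    precision = tp / len(flags)
    sensitivity = tp / n_gt if n_gt else None
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if sensitivity is not None and (precision + sensitivity) > 0
        else None
    )
    return DetectionEvalResult(precision, sensitivity, f1, ap)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC by sweeping thresholds over the unique scores; AUC by trapezoid.

    ``labels`` are binary (1 = positive).  AUC is invariant under strictly
    monotone transforms of the scores and equals the Mann-Whitney U statistic
    normalised by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise LengthMismatch("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels != 1).sum())
    if n_pos == 0 or n_neg == 0:
        raise OneClassOnly("both label values must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], (labels[order] == 1).astype(np.float64)
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep one operating point per distinct score (threshold = that score)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# Rater agreement
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    value: float
    degenerate: bool = False


def icc(table: np.ndarray | Sequence[Sequence[float]]) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``table`` is subjects x raters, complete (no missing cells).  Stage codes
    are ordinal (I=1, II=2, III/IV=3).  With the usual mean squares (rows MSR,
    columns MSC, residual MSE)::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    An all-identical table has no variance to apportion; it is reported as
    perfect agreement (value 1) with ``degenerate=True``.
    """
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("rater table must be complete")
    n, k = x.shape
    if np.ptp(x) == 0:
        return ICCResult(1.0, degenerate=True)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(1.0, degenerate=True)
    return ICCResult(float((msr - mse) / denom))


def rater_table(stage_lists: Sequence[Sequence[Stage]]) -> np.ndarray:
    """Stack per-rater stage sequences into a subjects x raters ordinal table."""
    lengths = {len(s) for s in stage_lists}
    if len(lengths) != 1:
        raise LengthMismatch("raters scored different numbers of subjects")
    return np.array([[s.ordinal for s in rater] for rater in stage_lists]).T


def chi_square_test(table: np.ndarray | Sequence[Sequence[float]]):
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)``; expected counts come from the row/column
    margins, without continuity correction.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ZeroMargin("a row or column margin is zero")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
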