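"""ROC evaluation of detection maps against reference masks.

For every score threshold, voxels at or above the cutoff are called tumor;
sensitivity and specificity are measured against a voxel-level reference
mask inside the evaluation domain (the prostate).  AUC is the trapezoidal
area under sensitivity vs 1-specificity.  Two Youden-style summaries are
reported: the headline ``yi`` is the maximum balanced accuracy
``(sensitivity + specificity) / 2`` (so a useless detector scores 0.5 and a
perfect one 1.0), and the classical Youden J ``sensitivity + specificity - 1``
is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending cutoffs (first is +inf anchor)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    yi: float  # max balanced accuracy
    yi_threshold: float
    youden_j: float  # max (sens + spec - 1), the classical index
    j_threshold: float
    n_positive: int
    n_negative: int


@dataclass
class CohortSummary:
    auc: list[float]
    yi: list[float]
    mean_auc: float
    se_auc: float
    mean_yi: float
    se_yi: float
    n: int


def roc_curve(scores, reference: np.ndarray, domain_mask: np.ndarray) -> ROCResult:
    """Threshold sweep of a detection map against a boolean reference.

    ``scores`` may be a DetectionMap or a plain array.  Ties share one
    threshold; the curve is anchored at (0,0) and (1,1); AUC uses the
    trapezoidal rule and equals the Mann-Whitney two-sample statistic.
    """
    s = np.asarray(getattr(scores, "scores", scores), dtype=float)
    domain = np.asarray(domain_mask, dtype=bool)
    ref = np.asarray(reference, dtype=bool) & domain
    y_true = ref[domain]
    y_score = s[domain]
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"reference must split the domain: {n_pos} positive / "
            f"{n_neg} negative voxels"
        )
    if np.ptp(y_score) == 0:
        # single-threshold degenerate curve: anchors only, chance AUC
        thresholds = np.array([np.inf, y_score[0]])
        sens = np.array([0.0, 1.0])
        spec = np.array([1.0, 0.0])
        return ROCResult(thresholds, sens, spec, 0.5, 0.5, float(y_score[0]),
                         0.0, float(y_score[0]), n_pos, n_neg)
    fpr, tpr, thr = skmetrics.roc_curve(y_true, y_score, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    balanced = (sens + spec) / 2.0
    # ties toward the lower threshold: thr is descending, so take the last argmax
    bi = int(balanced.size - 1 - np.argmax(balanced[::-1]))
    ji = int(balanced.size - 1 - np.argmax((sens - fpr)[::-1]))
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        yi=float(balanced[bi]),
        yi_threshold=float(thr[bi]),
        youden_j=float(sens[ji] - fpr[ji]),
        j_threshold=float(thr[ji]),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def cohort_summary(results: list[ROCResult]) -> CohortSummary:
    """Mean and standard error of AUC and YI over cases (divisor sqrt(n))."""
    n = len(results)
    if n < 2:
        raise ValueError("standard error undefined for fewer than 2 cases")
    auc = [r.auc for r in results]
    yi = [r.yi for r in results]
    return CohortSummary(
        auc=auc,
        yi=yi,
        mean_auc=float(np.mean(auc)),
        se_auc=float(np.std(auc, ddof=1) / np.sqrt(n)),
        mean_yi=float(np.mean(yi)),
        se_yi=float(np.std(yi, ddof=1) / np.sqrt(n)),
        n=n,
    )


def roc_to_table(result: ROCResult) -> "np.ndarray":
    """(threshold, sensitivity, 1-specificity) rows for CSV export."""
    return np.column_stack(
        [result.thresholds, result.sensitivity, 1.0 - result.specificity]
    )
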