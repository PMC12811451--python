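"""ROC evaluation of trajectory change scores against ground truth.

The positive class is *changing*. All positive calls use the strict
rule score > threshold, matching the trajectory classifiers, so every
ROC operating point is reproducible by thresholding. AUROC is the
trapezoidal area, which with tie-collapsed thresholds equals the
Mann–Whitney concordance (ties credited 1/2). The "optimal" operating
point maximizes Youden's J = sensitivity + specificity - 1; the
maximum-accuracy criterion is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError
from .scoring import ScoreParameters, ScoreResult
from .synthetic import CHANGING, STABLE


@dataclass(frozen=True)
class ROCResult:
    """ROC curve of one score against binary ground truth.

    ``thresholds`` are descending; point *i* is the operating point of
    the call rule score > thresholds[i]. The first threshold is the
    maximum score (nothing called positive, the (0,0) anchor) and the
    last is -inf (everything positive, the (1,1) anchor).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    optimal_threshold: Optional[float] = None
    optimal_sens: Optional[float] = None
    optimal_spec: Optional[float] = None
    optimal_acc: Optional[float] = None


@dataclass(frozen=True)
class MethodComparison:
    """Paired evaluation of the personalized (SNR) and population (VU) scores."""

    roc_personalized: ROCResult
    roc_population: ROCResult
    snr_cutoff_point: tuple[float, float, float]
    vu_cutoff_point: tuple[float, float, float]
    snr_cutoff: float
    vu_cutoff: float


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(labels)
    valid = np.isin(labels, (STABLE, CHANGING))
    if not valid.all():
        raise InvalidArgumentError(f"labels must be stable/changing, got {labels[~valid][:3]}")
    return labels == CHANGING


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> ROCResult:
    """Build the ROC of ``scores`` (changing = positive) by threshold scan.

    One point per distinct score value (ties collapsed) plus the
    all-positive anchor; AUROC by the trapezoidal rule.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.size != y.size:
        raise InvalidArgumentError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both classes present")

    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    # cumulative counts just above each distinct score, i.e. under score > s
    distinct_last = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(~y_sorted)
    thresholds = np.concatenate([s_sorted[distinct_last], [-np.inf]])
    tp = np.concatenate([[0], tp_cum[distinct_last]])
    fp = np.concatenate([[0], fp_cum[distinct_last]])
    tpr = tp / n_pos
    fpr = fp / n_neg
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auroc=auroc)


def optimal_threshold(
    roc: ROCResult,
    labels: Sequence[str] | None = None,
    criterion: Literal["youden", "accuracy"] = "youden",
    n_pos: int | None = None,
    n_neg: int | None = None,
) -> ROCResult:
    """Select the optimal operating point and return a completed ROCResult.

    Youden's J = tpr - fpr by default; ties break toward higher
    sensitivity, then toward the lower threshold. Accuracy at the chosen
    point uses the observed class mix (supply ``labels`` or the counts).
    """
    if labels is not None:
        y = _as_binary(labels)
        n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos is None or n_neg is None:
        raise InvalidArgumentError("class counts (or labels) are required for accuracy")
    n = n_pos + n_neg

    acc = (roc.tpr * n_pos + (1 - roc.fpr) * n_neg) / n
    objective = (roc.tpr - roc.fpr) if criterion == "youden" else acc
    if criterion not in ("youden", "accuracy"):
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")

    best = 0
    for i in range(1, len(objective)):
        if (
            objective[i] > objective[best] + 1e-12
            or (abs(objective[i] - objective[best]) <= 1e-12 and roc.tpr[i] > roc.tpr[best])
            or (
                abs(objective[i] - objective[best]) <= 1e-12
                and roc.tpr[i] == roc.tpr[best]
                and roc.thresholds[i] < roc.thresholds[best]
            )
        ):
            best = i
    return ROCResult(
        thresholds=roc.thresholds,
        tpr=roc.tpr,
        fpr=roc.fpr,
        auroc=roc.auroc,
        optimal_threshold=float(roc.thresholds[best]),
        optimal_sens=float(roc.tpr[best]),
        optimal_spec=float(1 - roc.fpr[best]),
        optimal_acc=float(acc[best]),
    )


def operating_point(
    scores: Sequence[float],
    labels: Sequence[str],
    threshold: float,
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of the call score > threshold."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if np.isnan(threshold):
        raise InvalidArgumentError("threshold must not be NaN")
    calls = scores > threshold
    tp = int(np.sum(calls & y))
    fn = int(np.sum(~calls & y))
    tn = int(np.sum(~calls & ~y))
    fp = int(np.sum(calls & ~y))
    if tp + fn == 0:
        warnings.warn("no positive labels: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative labels: specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    acc = (tp + tn) / y.size
    return sens, spec, acc


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[str],
    criterion: Literal["youden", "accuracy"] = "youden",
) -> ROCResult:
    """ROC plus optimal operating point in one call."""
    roc = roc_curve(scores, labels)
    return optimal_threshold(roc, labels=labels, criterion=criterion)


def compare_methods(
    cohort_scores: Sequence[ScoreResult],
    labels: Sequence[str],
    params: ScoreParameters | None = None,
    criterion: Literal["youden", "accuracy"] = "youden",
) -> MethodComparison:
    """Personalized (SNR) vs population (raw amplitude) ROC comparison.

    Also reports the fixed operating points at the SNR cutoff (default
    2.8, the laboratory-medicine RCV multiple) and the VU cutoff
    (default 10 VU).
    """
    params = params or ScoreParameters()
    snr_scores = [s.snr for s in cohort_scores]
    amp_scores = [s.pop_amplitude for s in cohort_scores]
    return MethodComparison(
        roc_personalized=evaluate_scores(snr_scores, labels, criterion),
        roc_population=evaluate_scores(amp_scores, labels, criterion),
        snr_cutoff_point=operating_point(snr_scores, labels, params.snr_cutoff),
        vu_cutoff_point=operating_point(amp_scores, labels, params.vu_cutoff),
        snr_cutoff=params.snr_cutoff,
        vu_cutoff=params.vu_cutoff,
    )
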