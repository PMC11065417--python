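"""ROC-based evaluation of ID-vs-OOD confidence scores.

Conventions, fixed so every number here is exactly testable:

* ID is the positive class; a sample is predicted ID iff its confidence
  score is >= the threshold (ties predict ID).
* The threshold sweep runs over the observed score values plus +/-inf, so the
  curve contains the (0, 0) and (1, 1) endpoints.
* AUROC is the trapezoidal area under that step curve, which equals the
  Mann-Whitney statistic P(s_ID > s_OOD) + 0.5 * P(s_ID = s_OOD).
* FPR95 is read off the curve without interpolation: the FPR at the largest
  threshold whose TPR reaches the level.
* The "best" operating point maximizes Youden's J = TPR - FPR; ties break
  toward higher TPR, then higher threshold.
* Quantiles in the five-number summary use linear interpolation between
  order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TypeVar

import numpy as np
from sklearn import metrics as _skm

T = TypeVar("T")


@dataclass
class ROCResult:
    """Threshold sweep (descending, +/-inf endpoints) with derived metrics."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    fpr95: float
    best_threshold: float
    best_tpr: float
    best_fpr: float


@dataclass(frozen=True)
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(a > b + 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("five-number summary must be non-decreasing")

    def as_dict(self) -> dict[str, float]:
        return {
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
        }


def _validate_scores(name: str, scores: np.ndarray) -> np.ndarray:
    arr = np.asarray(scores, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} scores must be non-empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} scores must be finite")
    return arr


def roc_curve(
    conf_id: np.ndarray, conf_ood: np.ndarray, tpr_level: float = 0.95
) -> ROCResult:
    """Sweep thresholds over ID (positive) vs OOD (negative) confidences."""
    s_id = _validate_scores("ID", conf_id)
    s_ood = _validate_scores("OOD", conf_ood)
    y = np.concatenate([np.ones(len(s_id)), np.zeros(len(s_ood))])
    s = np.concatenate([s_id, s_ood])
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    # sklearn starts the sweep at +inf; close it at -inf so both endpoints
    # (0,0) and (1,1) are explicit.
    thresholds = np.append(thr, -np.inf)
    tpr = np.append(tpr, 1.0)
    fpr = np.append(fpr, 1.0)
    auroc = float(np.trapezoid(tpr, fpr))
    fpr95 = _fpr_at_tpr_arrays(tpr, fpr, tpr_level)
    b_thr, b_tpr, b_fpr = _youden(thresholds, tpr, fpr)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auroc=auroc,
        fpr95=fpr95,
        best_threshold=b_thr,
        best_tpr=b_tpr,
        best_fpr=b_fpr,
    )


def _fpr_at_tpr_arrays(tpr: np.ndarray, fpr: np.ndarray, level: float) -> float:
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    idx = int(np.argmax(tpr >= level))  # first index: tpr is non-decreasing
    return float(fpr[idx])


def fpr_at_tpr(roc: ROCResult, level: float = 0.95) -> float:
    """FPR at the largest threshold whose TPR reaches ``level`` (no interpolation)."""
    return _fpr_at_tpr_arrays(roc.tpr, roc.fpr, level)


def _youden(
    thresholds: np.ndarray, tpr: np.ndarray, fpr: np.ndarray
) -> tuple[float, float, float]:
    j = tpr - fpr
    # lexicographic argmax: J, then TPR, then threshold (all maximized)
    order = np.lexsort((thresholds, tpr, j))
    k = order[-1]
    return float(thresholds[k]), float(tpr[k]), float(fpr[k])


def best_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = TPR - FPR.

    Ties break toward higher TPR, then higher threshold; in the separable
    case this returns the lowest ID score with (TPR, FPR) = (1, 0).
    """
    return _youden(roc.thresholds, roc.tpr, roc.fpr)


def accuracy_at_threshold(
    conf_id: np.ndarray, conf_ood: np.ndarray, threshold: float
) -> float:
    """Binary ID/OOD accuracy of the rule score >= threshold => ID."""
    s_id = _validate_scores("ID", conf_id)
    s_ood = _validate_scores("OOD", conf_ood)
    correct = int(np.sum(s_id >= threshold)) + int(np.sum(s_ood < threshold))
    return correct / (len(s_id) + len(s_ood))


def five_number_summary(scores: np.ndarray) -> FiveNumberSummary:
    """Min, quartiles (linear interpolation) and max of a score sample."""
    arr = _validate_scores("input", scores)
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumberSummary(*(float(v) for v in q))


def equalize_sizes(set_a: T, set_b: T, seed: int = 0) -> tuple[T, T]:
    """Subsample the larger of two sets so both have min(|a|, |b|) elements.

    Accepts numpy arrays or any container with ``__len__`` and ``take``
    (FeatureTable, ConfidenceSet).  Sampling is without replacement and
    deterministic given ``seed``; equal-sized inputs are returned unchanged.
    """
    na, nb = len(set_a), len(set_b)
    if na == 0 or nb == 0:
        raise ValueError("both sets must be non-empty")
    if na == nb:
        return set_a, set_b
    rng = np.random.default_rng(seed)
    size = min(na, nb)

    def _sub(obj, n_from):
        idx = np.sort(rng.choice(n_from, size=size, replace=False))
        if hasattr(obj, "take"):
            return obj.take(idx)
        return np.asarray(obj)[idx]

    if na > nb:
        return _sub(set_a, na), set_b
    return set_a, _sub(set_b, nb)
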