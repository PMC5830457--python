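"""ROC curves, AUC and operating-point (dynamic cutoff) selection.

This is the shared metric engine for every classifier in the package. The
positivity rule is fixed throughout: a subject is called positive when its
score is greater than or equal to the cutoff. Operating points are chosen at
achieved step-function values on the empirical curve — no interpolation
between thresholds. That choice is deliberate: cutoffs here are deployed as
thresholds on predicted probabilities, and an interpolated curve would hide
the collapse that occurs when a scorer (a pruned classification tree, say)
emits only a handful of distinct values.

Composite sequential models assign some subjects a score of exactly 1. The
threshold grid therefore always includes a ``+inf`` sentinel so the curve is
complete from (sens, spec) = (0, 1) to (1, 0) and a specificity floor is
always feasible, possibly at sensitivity 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoredCohort",
    "RocCurve",
    "OperatingPoint",
    "Constraint",
    "sens_spec_at_cutoff",
    "roc_curve",
    "auc",
    "cutoff_at_specificity",
    "cutoff_at_sensitivity",
]


class Constraint(str, enum.Enum):
    """Which metric an operating point constrains from below."""

    MIN_SPECIFICITY = "min_specificity"
    MIN_SENSITIVITY = "min_sensitivity"


@dataclass(frozen=True)
class ScoredCohort:
    """Per-subject scores (predicted probabilities or raw marker values)
    paired with true binary labels (1 = disease)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D of equal length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("ROC quantities need both classes present")


@dataclass(frozen=True)
class OperatingPoint:
    """A cutoff together with the sensitivity/specificity it achieves on the
    reference (model-building) scores it was selected on."""

    cutoff: float
    sensitivity: float
    specificity: float
    constraint: Constraint
    target: float


@dataclass
class RocCurve:
    """Empirical ROC step curve.

    ``thresholds`` descend from a ``+inf`` sentinel through the unique
    observed scores; ``sensitivity`` / ``specificity`` hold the achieved
    rates under the score >= threshold rule.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int = field(default=0)
    n_neg: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sens_spec_at_cutoff(sc: ScoredCohort, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule score >= cutoff.

    Sensitivity = TP / (TP + FN) over true positives, specificity =
    TN / (TN + FP) over true negatives.
    """
    sc.require_both_classes()
    pos = sc.labels == 1
    calls = sc.scores >= cutoff
    sensitivity = float(calls[pos].mean())
    specificity = float((~calls[~pos]).mean())
    return sensitivity, specificity


def _threshold_grid(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)[::-1]  # descending
    return np.concatenate(([np.inf], uniq))


def roc_curve(sc: ScoredCohort) -> RocCurve:
    """Empirical ROC curve over the +inf sentinel and all unique scores."""
    sc.require_both_classes()
    thresholds = _threshold_grid(sc.scores)
    pos_scores = np.sort(sc.scores[sc.labels == 1])
    neg_scores = np.sort(sc.scores[sc.labels == 0])
    # calls positive iff score >= t: count via searchsorted on sorted arrays
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    tp = n_pos - np.searchsorted(pos_scores, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_scores, thresholds, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens.astype(float),
        specificity=spec.astype(float),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve.

    On the empirical step curve this equals the tie-corrected Mann–Whitney
    probability P(score1 > score0) + 0.5 * P(score1 = score0).
    """
    fpr = 1.0 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def auc_scores(sc: ScoredCohort) -> float:
    """AUC computed directly from a scored cohort."""
    return auc(roc_curve(sc))


def cutoff_at_specificity(sc: ScoredCohort, target: float) -> OperatingPoint:
    """Smallest cutoff whose specificity meets the floor ``target``.

    Equivalently the cutoff of maximal sensitivity subject to
    specificity >= target. The +inf sentinel (specificity 1) guarantees a
    feasible choice, possibly with sensitivity 0 — which is exactly what
    happens to scorers with a large point mass among the negatives.
    """
    curve = roc_curve(sc)
    feasible = curve.specificity >= target
    idx = np.flatnonzero(feasible)
    # thresholds descend, specificity is non-increasing along the array,
    # so the last feasible index is the smallest feasible cutoff.
    i = idx[-1]
    return OperatingPoint(
        cutoff=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        constraint=Constraint.MIN_SPECIFICITY,
        target=target,
    )


def cutoff_at_sensitivity(sc: ScoredCohort, target: float) -> OperatingPoint:
    """Largest cutoff whose sensitivity meets the floor ``target``
    (maximal specificity subject to the sensitivity constraint). The
    minimum-score cutoff calls everyone positive, so feasibility is
    guaranteed."""
    curve = roc_curve(sc)
    feasible = curve.sensitivity >= target
    idx = np.flatnonzero(feasible)
    # sensitivity is non-decreasing as thresholds fall; the first feasible
    # index is the largest feasible cutoff.
    i = idx[0]
    return OperatingPoint(
        cutoff=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        constraint=Constraint.MIN_SENSITIVITY,
        target=target,
    )
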