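"""Sequential composite screening models: Fixed Sequential and Two-Step.

Both share one architecture: a high-specificity first split sends
screen-positive subjects straight to a predicted probability of exactly 1,
and a second-stage model scores everyone else. The resulting score
distribution has a point mass at 1 whose size equals the first-split
positive rate; the ROC engine's +inf threshold sentinel keeps the curve
complete despite that mass.

* Fixed Sequential (FS): the first split is serum AFP at the 20 ng/mL
  clinical screening threshold (positive at the boundary). The second
  stage is a logistic regression on all four biomarkers, trained only on
  the AFP-negative subjects of the training set. With the AFP cutoff at
  +inf, FS reduces exactly to plain logistic regression.

* Two-Step (TS): replaces the fixed AFP split with a learned one — a
  logistic regression over all four biomarkers thresholded at the cutoff
  achieving a target specificity (default 95%) on its own training scores
  — and the second-stage logistic model with a bagged random forest
  trained on the step-1-negative training subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import BIOMARKERS, Cohort
from .errors import DegenerateSplitError
from .learners import (
    CartResults,
    CartScreen,
    ForestResults,
    ForestScreen,
    LogisticResults,
    LogisticScreen,
)
from .roc import OperatingPoint, ScoredCohort, cutoff_at_specificity

__all__ = ["FixedSequential", "FixedSequentialResults", "TwoStep", "TwoStepResults"]

AFP_COLUMN = BIOMARKERS.index("serum_afp")


def _split_features(cohort_or_xy) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cohort_or_xy, Cohort):
        return cohort_or_xy.feature_matrix(), cohort_or_xy.labels
    raise TypeError("expected a Cohort")


class FixedSequential:
    """FS model: AFP >= cutoff (ng/mL) is called positive outright; the
    rest are scored by a logistic regression trained on the AFP-negative
    training subjects."""

    def __init__(self, cohort: Cohort, afp_cutoff: float = 20.0):
        if afp_cutoff <= 0:
            raise ValueError("afp_cutoff must be positive")
        self.X, self.y = _split_features(cohort)
        self.afp_cutoff = float(afp_cutoff)

    def fit(self) -> "FixedSequentialResults":
        afp_negative = self.X[:, AFP_COLUMN] < self.afp_cutoff
        X2, y2 = self.X[afp_negative], self.y[afp_negative]
        if len(X2) == 0 or len(np.unique(y2)) < 2:
            raise DegenerateSplitError(
                "AFP-negative training subset is empty or single-class"
            )
        second = LogisticScreen(y2, X2, feature_names=list(BIOMARKERS)).fit()
        return FixedSequentialResults(
            afp_cutoff=self.afp_cutoff, second_stage=second
        )


@dataclass(frozen=True)
class FixedSequentialResults:
    afp_cutoff: float
    second_stage: LogisticResults

    def predict(self, X) -> np.ndarray:
        """Probability 1 for AFP at/above the cutoff, else the second-stage
        logistic probability (strictly below 1)."""
        X = np.asarray(X, dtype=float)
        p = self.second_stage.predict(X)
        return np.where(X[:, AFP_COLUMN] >= self.afp_cutoff, 1.0, p)

    def summary(self) -> str:
        return (
            "Fixed Sequential model\n"
            f"  first split: serum AFP >= {self.afp_cutoff:g} ng/mL -> p = 1\n"
            "  second stage (AFP-negative subjects):\n"
            + "\n".join("  " + l for l in self.second_stage.summary().splitlines())
        )

    def to_dict(self) -> dict:
        return {
            "kind": "fixed_sequential",
            "afp_cutoff": self.afp_cutoff,
            "second_stage": self.second_stage.to_dict(),
        }


class TwoStep:
    """TS model: a 95%-specificity logistic first split, then a bagged
    forest trained on the step-1-negative training subjects."""

    def __init__(
        self,
        cohort: Cohort,
        spec_target: float = 0.95,
        ntree: int = 500,
        mtry: int = 2,
        train_second_on_all: bool = False,
    ):
        if not 0.0 <= spec_target <= 1.0:
            raise ValueError("spec_target must be in [0, 1]")
        self.X, self.y = _split_features(cohort)
        self.spec_target = spec_target
        self.ntree = ntree
        self.mtry = mtry
        self.train_second_on_all = train_second_on_all

    def fit(self, seed: int = 0) -> "TwoStepResults":
        first = LogisticScreen(self.y, self.X, feature_names=list(BIOMARKERS)).fit()
        train_scores = first.predict(self.X)
        op = cutoff_at_specificity(
            ScoredCohort(train_scores, self.y), self.spec_target
        )
        step1_negative = train_scores < op.cutoff
        if self.train_second_on_all:
            X2, y2 = self.X, self.y
        else:
            X2, y2 = self.X[step1_negative], self.y[step1_negative]
        if len(X2) == 0 or len(np.unique(y2)) < 2:
            raise DegenerateSplitError(
                "step-1-negative training subset is empty or single-class"
            )
        forest = ForestScreen(
            y2, X2, feature_names=list(BIOMARKERS), ntree=self.ntree, mtry=self.mtry
        ).fit(seed=seed)
        return TwoStepResults(
            first_stage=first, step1_cutoff=op, second_stage=forest
        )


@dataclass(frozen=True)
class TwoStepResults:
    first_stage: LogisticResults
    step1_cutoff: OperatingPoint
    second_stage: ForestResults

    def predict(self, X) -> np.ndarray:
        """Probability 1 when the first-stage score clears the learned
        cutoff, else the second-stage forest probability."""
        X = np.asarray(X, dtype=float)
        first = self.first_stage.predict(X)
        second = self.second_stage.predict(X)
        return np.where(first >= self.step1_cutoff.cutoff, 1.0, second)

    def summary(self) -> str:
        op = self.step1_cutoff
        return (
            "Two-Step model\n"
            f"  first split: LR score >= {op.cutoff:.4f} -> p = 1 "
            f"(training sens {op.sensitivity:.3f}, spec {op.specificity:.3f} "
            f"at target {op.target:.0%})\n"
            f"  second stage: bagged forest, "
            f"{len(self.second_stage.trees)} trees"
        )
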