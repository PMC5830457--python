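"""Repeated stratified 10-fold cross-validation of the five screening models.

Each iteration deals subjects into k stratified folds (per-class shuffle,
round-robin), trains all five models on every nine-fold building set, and
evaluates AUC plus dynamic operating points: for each specificity floor
(85/90/95%) the cutoff maximizing sensitivity is chosen on the building
scores and applied unchanged to the held-out fold, and symmetrically for
the sensitivity floors (90/95/99%). Per-iteration metrics are the
unweighted mean over the k folds (prediction pooling across folds is
available as an option); iterations are summarized by mean, percentile 95%
CI, median and range — the layout of the study's three results tables.

Degenerate composite fits inside a fold (e.g. a fold whose AFP-negative
subjects are single-class) are logged and excluded from that fold's mean
rather than aborting a long run; missingness is counted in the results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS, Cohort
from .composite import FixedSequential, TwoStep
from .errors import DegenerateSplitError
from .learners import CartScreen, ForestScreen, LogisticScreen
from .roc import (
    ScoredCohort,
    auc_scores,
    cutoff_at_sensitivity,
    cutoff_at_specificity,
    sens_spec_at_cutoff,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "stratified_folds",
    "run_iteration",
    "summarize",
    "CrossValidationStudy",
    "CrossValidationResults",
]

MODEL_NAMES = ("LR", "CART", "FS", "RF", "TS")
SPECIFICITY_TARGETS = (0.85, 0.90, 0.95)
SENSITIVITY_TARGETS = (0.90, 0.95, 0.99)

# fixed per-model seed offsets so model streams never collide
_MODEL_SEED_OFFSET = {"CART": 1_000_003, "RF": 2_000_003, "TS": 3_000_003}


@dataclass(frozen=True)
class FoldAssignment:
    fold_index: np.ndarray  # per subject, in {0..k-1}
    k: int
    seed: int


def stratified_fold_indices(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Round-robin deal of shuffled subjects into k folds within each class.

    Per-class fold counts differ by at most one. No minimum class size is
    enforced here; use :func:`stratified_folds` for the validated public
    contract.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def stratified_folds(cohort: Cohort, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment for a cohort (classes = HCC / non-HCC)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    y = cohort.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than k={k}"
        )
    return FoldAssignment(stratified_fold_indices(y, k, seed), k=k, seed=seed)


# ---------------------------------------------------------------------------
# model fitting dispatch


def _fit_and_score(
    name: str,
    X_build: np.ndarray,
    y_build: np.ndarray,
    cohort_build: Cohort,
    X_val: np.ndarray,
    seed: int,
    model_params: dict,
):
    """Fit one named model on the building set; return (build, val) scores."""
    if name == "LR":
        res = LogisticScreen(y_build, X_build, feature_names=list(BIOMARKERS)).fit()
    elif name == "CART":
        res = CartScreen(y_build, X_build, feature_names=list(BIOMARKERS)).fit(
            k_internal=model_params.get("cart_k_internal", 10),
            seed=seed + _MODEL_SEED_OFFSET["CART"],
        )
    elif name == "RF":
        res = ForestScreen(
            y_build,
            X_build,
            feature_names=list(BIOMARKERS),
            ntree=model_params.get("ntree", 500),
            mtry=model_params.get("mtry", 2),
        ).fit(seed=seed + _MODEL_SEED_OFFSET["RF"])
    elif name == "FS":
        res = FixedSequential(
            cohort_build, afp_cutoff=model_params.get("afp_cutoff", 20.0)
        ).fit()
    elif name == "TS":
        res = TwoStep(
            cohort_build,
            spec_target=model_params.get("ts_spec_target", 0.95),
            ntree=model_params.get("ntree", 500),
            mtry=model_params.get("mtry", 2),
        ).fit(seed=seed + _MODEL_SEED_OFFSET["TS"])
    else:
        raise ValueError(f"unknown model {name!r}")
    return res.predict(X_build), res.predict(X_val)


def _metric_names() -> list[str]:
    names = ["building_auc", "validation_auc"]
    for t in SPECIFICITY_TARGETS:
        names += [f"building_sens_at_spec{int(round(t * 100))}",
                  f"validation_sens_at_spec{int(round(t * 100))}"]
    for t in SENSITIVITY_TARGETS:
        names += [f"building_spec_at_sens{int(round(t * 100))}",
                  f"validation_spec_at_sens{int(round(t * 100))}"]
    return names


METRIC_NAMES = tuple(_metric_names())


@dataclass
class IterationResult:
    """Fold-averaged metrics for one CV iteration: metrics[model][metric]."""

    metrics: dict
    n_failed_folds: dict
    cutoffs: dict = field(default_factory=dict)


def _fold_metrics(sc_build: ScoredCohort, sc_val: ScoredCohort) -> dict:
    out = {
        "building_auc": auc_scores(sc_build),
        "validation_auc": auc_scores(sc_val),
    }
    for t in SPECIFICITY_TARGETS:
        op = cutoff_at_specificity(sc_build, t)
        v_sens, _ = sens_spec_at_cutoff(sc_val, op.cutoff)
        tag = int(round(t * 100))
        out[f"building_sens_at_spec{tag}"] = op.sensitivity
        out[f"validation_sens_at_spec{tag}"] = v_sens
        out[f"cutoff_spec{tag}"] = op.cutoff
    for t in SENSITIVITY_TARGETS:
        op = cutoff_at_sensitivity(sc_build, t)
        _, v_spec = sens_spec_at_cutoff(sc_val, op.cutoff)
        tag = int(round(t * 100))
        out[f"building_spec_at_sens{tag}"] = op.specificity
        out[f"validation_spec_at_sens{tag}"] = v_spec
        out[f"cutoff_sens{tag}"] = op.cutoff
    return out


def run_iteration(
    cohort: Cohort,
    folds: FoldAssignment,
    models: tuple = MODEL_NAMES,
    seed: int = 0,
    model_params: dict | None = None,
    pool_folds: bool = False,
    labels: np.ndarray | None = None,
) -> IterationResult:
    """One pass of k-fold CV: per fold, train every model on the other
    folds, pick dynamic cutoffs on building scores, apply them to the held
    fold; average metrics over folds (or pool predictions when
    ``pool_folds``). ``labels`` overrides the cohort's labels (used by the
    permutation negative control)."""
    model_params = model_params or {}
    X = cohort.feature_matrix()
    y = cohort.labels if labels is None else np.asarray(labels)
    per_model: dict = {m: [] for m in models}
    pooled: dict = {m: ([], []) for m in models}
    n_failed = {m: 0 for m in models}
    for f in range(folds.k):
        val = folds.fold_index == f
        build_cohort = cohort.subset(~val)
        if labels is not None:
            # carry permuted labels through the Cohort interface
            build_cohort.data = build_cohort.data.assign(
                label=y[~val],
                disease_group=np.where(y[~val] == 1, "HCC", "cirrhosis"),
            )
        for m in models:
            try:
                s_build, s_val = _fit_and_score(
                    m, X[~val], y[~val], build_cohort, X[val], seed, model_params
                )
            except DegenerateSplitError as exc:
                logger.info("fold %d model %s degenerate: %s", f, m, exc)
                n_failed[m] += 1
                continue
            if pool_folds:
                pooled[m][0].append(s_val)
                pooled[m][1].append(y[val])
            per_model[m].append(
                _fold_metrics(
                    ScoredCohort(s_build, y[~val]), ScoredCohort(s_val, y[val])
                )
            )
    metrics = {}
    for m in models:
        fold_results = per_model[m]
        if not fold_results:
            metrics[m] = {k: np.nan for k in METRIC_NAMES}
            continue
        metrics[m] = {
            k: float(np.mean([fr[k] for fr in fold_results])) for k in METRIC_NAMES
        }
        if pool_folds:
            sc = ScoredCohort(
                np.concatenate(pooled[m][0]), np.concatenate(pooled[m][1])
            )
            metrics[m]["validation_auc_pooled"] = auc_scores(sc)
    cutoffs = {
        m: {
            k: [fr[k] for fr in per_model[m]]
            for k in per_model[m][0]
            if k.startswith("cutoff_")
        }
        for m in models
        if per_model[m]
    }
    return IterationResult(metrics=metrics, n_failed_folds=n_failed, cutoffs=cutoffs)


def summarize(values) -> dict:
    """Mean, percentile (2.5/97.5, linear interpolation) 95% CI, median and
    range of a vector of per-iteration metric values."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("no values to summarize")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return {
        "mean": float(values.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


class CrossValidationStudy:
    """Repeated stratified k-fold CV comparison of the screening models.

    ``fit(iterations, base_seed)`` runs the full experiment (iteration i
    uses seed ``base_seed + i`` for its folds and model randomness) and
    returns a :class:`CrossValidationResults`.
    """

    def __init__(
        self,
        cohort: Cohort,
        models: tuple = MODEL_NAMES,
        k: int = 10,
        model_params: dict | None = None,
    ):
        cohort.require_both_classes()
        self.cohort = cohort
        self.models = tuple(models)
        self.k = k
        self.model_params = model_params or {}

    def fit(
        self,
        iterations: int = 1000,
        base_seed: int = 0,
        pool_folds: bool = False,
        progress: bool = False,
    ) -> "CrossValidationResults":
        records = []
        failures = {m: 0 for m in self.models}
        for i in range(iterations):
            seed = base_seed + i
            folds = stratified_folds(self.cohort, self.k, seed)
            res = run_iteration(
                self.cohort,
                folds,
                models=self.models,
                seed=seed,
                model_params=self.model_params,
                pool_folds=pool_folds,
            )
            for m in self.models:
                failures[m] += res.n_failed_folds[m]
                row = {"iteration": i, "model": m}
                row.update(res.metrics[m])
                records.append(row)
            if progress:
                logger.info("iteration %d/%d complete", i + 1, iterations)
        return CrossValidationResults(
            iteration_table=pd.DataFrame.from_records(records),
            models=self.models,
            k=self.k,
            iterations=iterations,
            base_seed=base_seed,
            n_failed_folds=failures,
        )


@dataclass
class CrossValidationResults:
    """Per-iteration metric table plus the three summary tables."""

    iteration_table: pd.DataFrame
    models: tuple
    k: int
    iterations: int
    base_seed: int
    n_failed_folds: dict

    def _summary_table(self, metric_pairs: list[tuple[str, str, str]]) -> pd.DataFrame:
        rows = []
        for label, build_col, val_col in metric_pairs:
            for m in self.models:
                sub = self.iteration_table[self.iteration_table["model"] == m]
                row = {"cutoff": label, "model": m}
                for phase, col in (("building", build_col), ("validation", val_col)):
                    s = summarize(sub[col])
                    row.update({f"{phase}_{k}": v for k, v in s.items()})
                rows.append(row)
        return pd.DataFrame(rows)

    @property
    def auc_table(self) -> pd.DataFrame:
        """Model-building and validation AUC summaries (one row per model)."""
        t = self._summary_table([("AUC", "building_auc", "validation_auc")])
        return t.drop(columns="cutoff")

    @property
    def sensitivity_table(self) -> pd.DataFrame:
        """Sensitivity at the 85/90/95% specificity floors."""
        pairs = [
            (
                f"{tag}% specificity",
                f"building_sens_at_spec{tag}",
                f"validation_sens_at_spec{tag}",
            )
            for tag in (85, 90, 95)
        ]
        return self._summary_table(pairs)

    @property
    def specificity_table(self) -> pd.DataFrame:
        """Specificity at the 90/95/99% sensitivity floors."""
        pairs = [
            (
                f"{tag}% sensitivity",
                f"building_spec_at_sens{tag}",
                f"validation_spec_at_sens{tag}",
            )
            for tag in (90, 95, 99)
        ]
        return self._summary_table(pairs)

    def validation_mean_auc(self) -> dict:
        t = self.auc_table
        return dict(zip(t["model"], t["validation_mean"]))

    def summary(self) -> str:
        def fmt(t: pd.DataFrame, title: str) -> str:
            lines = [title]
            for _, r in t.iterrows():
                cut = f"{r['cutoff']:<18}" if "cutoff" in r else ""
                lines.append(
                    f"  {cut}{r['model']:<6}"
                    f"build {r['building_mean']:.3f} "
                    f"({r['building_ci_low']:.3f}-{r['building_ci_high']:.3f})  "
                    f"val {r['validation_mean']:.3f} "
                    f"({r['validation_ci_low']:.3f}-{r['validation_ci_high']:.3f})"
                )
            return "\n".join(lines)

        head = (
            f"Repeated stratified {self.k}-fold cross-validation, "
            f"{self.iterations} iterations (base seed {self.base_seed})"
        )
        return "\n".join(
            [
                head,
                fmt(self.auc_table, "AUC"),
                fmt(self.sensitivity_table, "Sensitivity at specificity floors"),
                fmt(self.specificity_table, "Specificity at sensitivity floors"),
            ]
        )

    def write_tables(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.auc_table.to_csv(outdir / "cv_auc.csv", index=False)
        self.sensitivity_table.to_csv(outdir / "cv_sensitivity.csv", index=False)
        self.specificity_table.to_csv(outdir / "cv_specificity.csv", index=False)
        manifest = {
            "models": list(self.models),
            "k": self.k,
            "iterations": self.iterations,
            "base_seed": self.base_seed,
            "n_failed_folds": self.n_failed_folds,
        }
        import json

        (outdir / "cv_manifest.json").write_text(json.dumps(manifest, indent=2))
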