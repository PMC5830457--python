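"""Univariate and correlation analyses of the cohort.

Covers the marker-by-marker comparisons between HCC and controls
(Wilcoxon rank sum, box-plot summaries, univariate logistic ROC/AUC) and
the weak-confounding checks between markers and demographics (Spearman
correlation with age, point-biserial correlation with gender on
log-transformed marker levels). All correlation analyses use
pairwise-complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import BIOMARKERS, Cohort
from .errors import UndefinedCorrelationError
from .learners import LogisticScreen
from .roc import ScoredCohort, auc_scores

__all__ = [
    "wilcoxon_rank_sum",
    "spearman_corr",
    "point_biserial_log",
    "univariate_auc",
    "boxplot_stats",
    "correlation_report",
    "marker_tests",
]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration for small untied samples (m + n <= 20), otherwise
    the normal approximation with midranks, tie correction and continuity
    correction — the behaviour of standard statistical packages at this
    study's sample sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def spearman_corr(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks) over
    pairwise-complete observations."""
    x, y = _pairwise_complete(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairwise-complete pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def point_biserial_log(marker, group, offset: float = 1.0) -> float:
    """Point-biserial correlation between a binary grouping and
    ln(marker + offset). The unit offset admits the zero (not-detected)
    marker values."""
    marker = np.asarray(marker, dtype=float)
    group = np.asarray(group, dtype=float)
    marker, group = _pairwise_complete(marker, group)
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be non-empty")
    transformed = np.log(marker + offset)
    if len(np.unique(transformed)) < 2:
        raise UndefinedCorrelationError("log-transformed marker is constant")
    return float(sps.pearsonr(group, transformed).statistic)


def univariate_auc(marker, labels) -> float:
    """AUC of a single-biomarker logistic regression.

    The logistic transform is monotone, so with a positive slope this
    equals the rank AUC of the raw marker; fitting the model keeps the
    route identical to the multivariate analyses.
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    if len(np.unique(marker)) < 2:
        return 0.5
    res = LogisticScreen(labels, marker[:, None]).fit()
    return auc_scores(ScoredCohort(res.predict(marker[:, None]), labels))


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_stats(values) -> BoxplotStats:
    """Five-number box-plot summary with Tukey 1.5*IQR whiskers.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme observation inside the fences, outliers are everything beyond.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(values[(values < lo_fence) | (values > hi_fence)]),
    )


def marker_tests(cohort: Cohort) -> pd.DataFrame:
    """Per-marker HCC vs non-HCC comparison: Wilcoxon p and univariate AUC."""
    y = cohort.labels
    rows = []
    for name in BIOMARKERS:
        v = cohort.marker(name)
        rows.append(
            {
                "marker": name,
                "wilcoxon_p": wilcoxon_rank_sum(v[y == 1], v[y == 0]),
                "auc": univariate_auc(v, y),
            }
        )
    return pd.DataFrame(rows)


def correlation_report(cohort: Cohort) -> pd.DataFrame:
    """Marker vs demographic correlations: Spearman rho against age and
    point-biserial (male = 1) against ln(marker + 1), with the
    pairwise-complete n used for each."""
    df = cohort.data
    age = df["age"].to_numpy(dtype=float)
    gender = df["gender"].map({"male": 1.0, "female": 0.0}).to_numpy(dtype=float)
    rows = []
    for name in BIOMARKERS:
        v = cohort.marker(name)
        va, aa = _pairwise_complete(v, age)
        vg, gg = _pairwise_complete(v, gender)
        rows.append(
            {
                "marker": name,
                "spearman_age": spearman_corr(va, aa),
                "n_age": len(va),
                "point_biserial_gender": point_biserial_log(vg, gg),
                "n_gender": len(vg),
            }
        )
    return pd.DataFrame(rows)
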