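"""Reading, validating and summarizing subject-level biomarker cohorts.

A cohort is one row per subject: disease group (HCC, cirrhosis or
hepatitis), the four biomarker levels — three urine DNA markers (TP53 249T
mutation, aberrantly methylated RASSF1A and GSTP1) plus serum AFP in ng/mL —
and optional demographics (age, gender, HBV and HCV status) that may be
missing. The binary modeling label is 1 for HCC and 0 for the pooled
cirrhosis/hepatitis controls.

Modeling uses complete biomarker rows only; demographics are kept with
explicit missingness and excluded pairwise per analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortFormatError, DegenerateGroupError, EmptyCohortError

logger = logging.getLogger(__name__)

BIOMARKERS = ("tp53_249t", "mrassf1a", "mgstp1", "serum_afp")
DISEASE_GROUPS = ("HCC", "cirrhosis", "hepatitis")
REQUIRED_COLUMNS = ("subject_id", "disease_group") + BIOMARKERS
DEMOGRAPHICS = ("age", "gender", "hbv", "hcv")

_GENDER_MAP = {"male": "male", "m": "male", "female": "female", "f": "female"}
_POSNEG_MAP = {
    "positive": "positive", "pos": "positive", "+": "positive", "1": "positive",
    "negative": "negative", "neg": "negative", "-": "negative", "0": "negative",
}


@dataclass
class Cohort:
    """An ordered collection of subject records backed by a DataFrame.

    Columns: ``subject_id``, ``disease_group``, the four biomarkers,
    ``age``, ``gender``, ``hbv``, ``hcv``. A derived ``label`` column is 1
    iff the disease group is HCC.
    """

    data: pd.DataFrame
    provenance: str = "unspecified"
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self._validated:
            self.data = _validate_frame(self.data)
            self._validated = True

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    @property
    def n_hcc(self) -> int:
        return int(self.labels.sum())

    @property
    def n_non_hcc(self) -> int:
        return len(self) - self.n_hcc

    def feature_matrix(self) -> np.ndarray:
        """The biomarker matrix in fixed column order (see BIOMARKERS)."""
        return self.data.loc[:, list(BIOMARKERS)].to_numpy(dtype=float)

    @property
    def serum_afp(self) -> np.ndarray:
        return self.data["serum_afp"].to_numpy(dtype=float)

    def marker(self, name: str) -> np.ndarray:
        if name not in BIOMARKERS:
            raise KeyError(f"unknown biomarker {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "Cohort":
        sub = Cohort.__new__(Cohort)
        sub.data = self.data.loc[np.asarray(mask)].reset_index(drop=True)
        sub.provenance = provenance or self.provenance
        sub._validated = True
        return sub

    def require_both_classes(self) -> None:
        if self.n_hcc == 0 or self.n_non_hcc == 0:
            raise EmptyCohortError(
                "modeling requires at least one HCC and one non-HCC subject"
            )


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"missing required column {col!r}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortFormatError(f"duplicate subject_id {dup!r}")
    bad_group = ~df["disease_group"].isin(DISEASE_GROUPS)
    if bad_group.any():
        raise CohortFormatError(
            f"unknown disease_group value {df.loc[bad_group, 'disease_group'].iloc[0]!r}"
        )
    for col in BIOMARKERS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    complete = df.loc[:, list(BIOMARKERS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing biomarker values", n_dropped)
        df = df.loc[complete]
    if df.empty:
        raise EmptyCohortError("no rows with complete biomarker values")
    for col in BIOMARKERS:
        if (df[col] < 0).any():
            raise CohortFormatError(f"negative values in biomarker column {col!r}")
    for col in DEMOGRAPHICS:
        if col not in df.columns:
            df[col] = np.nan if col == "age" else pd.NA
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["gender"] = _normalize_categorical(df["gender"], _GENDER_MAP, "gender")
    for col in ("hbv", "hcv"):
        df[col] = _normalize_categorical(df[col], _POSNEG_MAP, col)
    df["label"] = (df["disease_group"] == "HCC").astype(int)
    return df.reset_index(drop=True)


def _normalize_categorical(s: pd.Series, mapping: dict, name: str) -> pd.Series:
    def norm(v):
        if pd.isna(v) or (isinstance(v, str) and not v.strip()):
            return pd.NA
        key = str(v).strip().lower()
        if key in mapping:
            return mapping[key]
        logger.info("unrecognized %s value %r mapped to missing", name, v)
        return pd.NA

    return s.map(norm)


def read_cohort(path, format: str = "csv", provenance: str | None = None) -> Cohort:
    """Read a cohort table from CSV.

    Blank cells and unrecognized demographic codes are mapped to missing
    (and logged); rows lacking any of the four biomarker values are dropped
    with a logged count. Raises :class:`CohortFormatError` if a required
    column is absent and :class:`EmptyCohortError` if no usable rows remain.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return Cohort(df, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV.

    Biomarker floats are written with ``repr`` precision so a read/write
    cycle reproduces them bit-exactly.
    """
    cols = list(REQUIRED_COLUMNS) + list(DEMOGRAPHICS)
    out = cohort.data.loc[:, cols].copy()
    for col in BIOMARKERS:
        out[col] = out[col].map(repr)  # shortest exact float representation
    out.to_csv(path, index=False)


def _binary_rows(df: pd.DataFrame, col: str, positive: str):
    present = df[col].notna()
    n_pos = int((df.loc[present, col] == positive).sum())
    return int(present.sum()), n_pos


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Descriptive study-population table: HCC vs non-HCC demographics.

    For age: n (and missing-n), mean (SD), median (range), and a two-sided
    Welch t-test p-value. For gender/HBV/HCV: n, count and percent positive
    (male, HBV+, HCV+), and a continuity-corrected chi-square p-value on
    the 2x2 table (matching R's default ``chisq.test``).
    """
    df = cohort.data
    groups = {"HCC": df[df["label"] == 1], "non-HCC": df[df["label"] == 0]}
    for name, g in groups.items():
        if len(g) == 0:
            raise DegenerateGroupError(f"group {name} has no subjects")

    rows = []
    ages = {k: g["age"].dropna() for k, g in groups.items()}
    t_p = float(
        stats.ttest_ind(ages["HCC"], ages["non-HCC"], equal_var=False).pvalue
    )
    rows.append(
        {
            "variable": "age",
            "statistic": "n (missing)",
            "HCC": f"{len(ages['HCC'])} ({int(groups['HCC']['age'].isna().sum())})",
            "non-HCC": f"{len(ages['non-HCC'])} ({int(groups['non-HCC']['age'].isna().sum())})",
            "p_value": t_p,
        }
    )
    for stat_name, fn in (
        ("mean (SD)", lambda a: f"{a.mean():.1f} ({a.std(ddof=1):.1f})"),
        ("median (range)", lambda a: f"{a.median():.1f} ({a.min():.1f}-{a.max():.1f})"),
    ):
        rows.append(
            {
                "variable": "age",
                "statistic": stat_name,
                "HCC": fn(ages["HCC"]),
                "non-HCC": fn(ages["non-HCC"]),
                "p_value": np.nan,
            }
        )

    for var, positive, pos_label in (
        ("gender", "male", "male"),
        ("hbv", "positive", "positive"),
        ("hcv", "positive", "positive"),
    ):
        counts = {}
        for name, g in groups.items():
            counts[name] = _binary_rows(g, var, positive)
        table = np.array(
            [
                [counts["HCC"][1], counts["HCC"][0] - counts["HCC"][1]],
                [counts["non-HCC"][1], counts["non-HCC"][0] - counts["non-HCC"][1]],
            ]
        )
        p = chi_square_2x2(table)
        rows.append(
            {
                "variable": var,
                "statistic": "n (missing)",
                "HCC": f"{counts['HCC'][0]} ({len(groups['HCC']) - counts['HCC'][0]})",
                "non-HCC": f"{counts['non-HCC'][0]} ({len(groups['non-HCC']) - counts['non-HCC'][0]})",
                "p_value": p,
            }
        )
        rows.append(
            {
                "variable": var,
                "statistic": f"{pos_label}: n (%)",
                "HCC": f"{counts['HCC'][1]} ({100 * counts['HCC'][1] / counts['HCC'][0]:.0f}%)",
                "non-HCC": f"{counts['non-HCC'][1]} ({100 * counts['non-HCC'][1] / counts['non-HCC'][0]:.0f}%)",
                "p_value": np.nan,
            }
        )
    return pd.DataFrame(rows)


def chi_square_2x2(table: np.ndarray, correction: bool = True) -> float:
    """Chi-square p-value on a 2x2 contingency table.

    Yates' continuity correction is applied by default, matching the
    convention of R's ``chisq.test`` used for the study-population table.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return float(stats.chi2_contingency(table, correction=correction)[1])
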