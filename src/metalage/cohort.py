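"""Cohort table schema, validation, readers/writers, and exclusion cascade.

The analysis operates on a flat participant-level table ("cohort"): one row per
participant carrying the nine urinary metals, urinary creatinine, the two
clinical biomarker panels used by the aging scores, leukocyte telomere length,
self-reported osteoarthritis status, covariates and a survey weight.  The
column schema is fixed and validated on load so every downstream stage can
rely on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A cohort table does not conform to the documented column schema."""


class DataError(ValueError):
    """A cohort table conforms to the schema but contains invalid values."""


#: Nine urinary metals measured by ICP-MS in spot urine (identifiers follow
#: the element symbols; "tu" is uranium as labelled in the source data).
METALS: tuple[str, ...] = ("ba", "cd", "co", "cs", "mo", "pb", "sb", "tl", "tu")

METAL_COLUMNS: tuple[str, ...] = tuple(f"metal_{m}" for m in METALS)

#: Eight biomarkers entering the Klemera-Doubal biological age.
#: Units: lncrp Ln(mg/dL), creat mg/dL (serum), hba1c %, albumin g/dL,
#: chol mg/dL, bun mg/dL, alp U/L, sbp mmHg.
KDM_BIOMARKERS: tuple[str, ...] = (
    "kdm_lncrp",
    "kdm_creat",
    "kdm_hba1c",
    "kdm_albumin",
    "kdm_chol",
    "kdm_bun",
    "kdm_alp",
    "kdm_sbp",
)

#: Nine biomarkers entering the phenotypic age closed form, stored in the
#: formula's units: albumin g/L, creatinine umol/L, glucose mmol/L,
#: lncrp Ln(mg/dL), lymphocyte %, mean cell volume fL, red-cell distribution
#: width %, alkaline phosphatase U/L, white-cell count 10^9/L.
PHENO_BIOMARKERS: tuple[str, ...] = (
    "pheno_albumin",
    "pheno_creat",
    "pheno_glucose",
    "pheno_lncrp",
    "pheno_lymph",
    "pheno_mcv",
    "pheno_rdw",
    "pheno_alp",
    "pheno_wbc",
)

CATEGORICAL_COVARIATES: tuple[str, ...] = (
    "sex",
    "race",
    "education",
    "marital",
    "activity",
    "alcohol",
)
CONTINUOUS_COVARIATES: tuple[str, ...] = ("age", "bmi", "pir", "cotinine")
COVARIATES: tuple[str, ...] = CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES

RACE_LEVELS = (
    "mexican_american",
    "other_hispanic",
    "nh_white",
    "nh_black",
    "other",
)
EDUCATION_LEVELS = ("under_hs", "hs", "above_hs")
MARITAL_LEVELS = ("married", "wid_div_sep", "never")
ACTIVITY_LEVELS = ("moderate", "vigorous")
ALCOHOL_LEVELS = ("never", "ever")
SEX_LEVELS = ("male", "female")

REQUIRED_COLUMNS: tuple[str, ...] = (
    ("participant_id",)
    + METAL_COLUMNS
    + ("creatinine_mgdl", "oa")
    + COVARIATES
    + KDM_BIOMARKERS
    + PHENO_BIOMARKERS
    + ("telomere_ts", "survey_weight")
)

#: Columns added by the aging module.
MARKER_COLUMNS: tuple[str, ...] = ("biological_age", "phenotypic_age", "telomere_ts")


def validate_cohort(cohort: pd.DataFrame, *, allow_missing: bool = True) -> pd.DataFrame:
    """Check the fixed column schema and basic value invariants.

    Missing values (NaN) are tolerated when ``allow_missing`` — the exclusion
    cascade and covariate imputation handle them — but structural violations
    (absent columns, non-binary outcome, non-positive weights) raise.
    """
    if cohort is None or len(cohort) == 0:
        raise SchemaError("cohort table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort is missing mandatory columns: {missing}")
    oa = cohort["oa"].dropna()
    if not oa.isin([0, 1]).all():
        raise DataError("oa must be binary (0/1)")
    w = cohort["survey_weight"].dropna()
    if (w <= 0).any():
        raise DataError("survey_weight must be strictly positive")
    ts = cohort["telomere_ts"].dropna()
    if (ts <= 0).any():
        raise DataError("telomere_ts must be strictly positive")
    if not allow_missing:
        core = list(METAL_COLUMNS) + ["creatinine_mgdl", "oa"]
        if cohort[core].isna().any().any():
            raise DataError("missing values present in metals/creatinine/outcome")
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV with the documented header."""
    cohort.to_csv(path, index=False)


def read_cohort(
    path: str | Path | Sequence[str | Path],
    format: str = "csv",
    schema_map: Mapping[str, str] | None = None,
    merge_on: str = "SEQN",
) -> pd.DataFrame:
    """Read and validate a cohort table.

    Parameters
    ----------
    path
        A CSV file, or for ``format="xpt-set"`` one or more SAS transport
        (XPT v5) files that are merged on ``merge_on`` (the survey's
        respondent sequence number) before renaming.
    format
        ``"csv"`` or ``"xpt-set"``.
    schema_map
        Mapping from source variable names to the documented schema names;
        required for XPT input, optional renaming for CSV.
    """
    if format == "csv":
        df = pd.read_csv(path)
        if schema_map:
            df = df.rename(columns=dict(schema_map))
    elif format == "xpt-set":
        paths = [path] if isinstance(path, (str, Path)) else list(path)
        if schema_map is None:
            raise SchemaError("xpt-set input requires a schema_map")
        frames = [pd.read_sas(p, format="xport") for p in paths]
        df = frames[0]
        for f in frames[1:]:
            df = df.merge(f, on=merge_on, how="outer")
        df = df.rename(columns=dict(schema_map))
        if "participant_id" not in df.columns and merge_on in df.columns:
            df = df.rename(columns={merge_on: "participant_id"})
    else:
        raise ValueError(f"unknown format {format!r}")
    log.info("read cohort: %d rows, %d columns", len(df), df.shape[1])
    return validate_cohort(df)


@dataclass(frozen=True)
class ExclusionLog:
    """One stage of the participant-selection cascade."""

    stage: str
    n_before: int
    n_excluded: int
    n_after: int
    reason: str

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_excluded:
            raise ValueError("exclusion log does not balance")


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list[ExclusionLog]]:
    """Apply the study's exclusion cascade.

    Rows missing any of the nine urinary metals are dropped first, then rows
    missing urinary creatinine (required for dilution correction).  The
    chained log mirrors a participant-flow diagram.
    """
    validate_cohort(cohort)
    logs: list[ExclusionLog] = []
    n0 = len(cohort)
    keep = cohort[list(METAL_COLUMNS)].notna().all(axis=1)
    step1 = cohort.loc[keep]
    logs.append(
        ExclusionLog("metals_complete", n0, n0 - len(step1), len(step1),
                     "missing one or more of the 9 urinary metals")
    )
    keep2 = step1["creatinine_mgdl"].notna() & (step1["creatinine_mgdl"] > 0)
    step2 = step1.loc[keep2]
    logs.append(
        ExclusionLog("creatinine_present", len(step1), len(step1) - len(step2),
                     len(step2), "missing or non-positive urinary creatinine")
    )
    if len(step2) == 0:
        raise DataError("all participants excluded")
    for entry in logs:
        log.info("exclusion %s: %d -> %d (-%d)", entry.stage, entry.n_before,
                 entry.n_after, entry.n_excluded)
    return step2.reset_index(drop=True), logs
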