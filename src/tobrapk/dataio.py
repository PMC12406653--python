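"""Reading, writing and validation of the NONMEM-style longitudinal CSV dialect.

One row per event.  Dose rows (EVID=1) carry AMT (mg) and the documented
infusion duration DUR (h); observation rows (EVID=0) carry DV (mg/L), MDV and
the BLQ censoring flag.  Covariates repeat on every row of a subject and the
column names declare their units (AGE_YR, WT_KG, HT_M, SCR_UMOLL or SCR_MGDL,
GA_WK) — a creatinine column without a unit suffix is rejected outright.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DatasetValidationError",
    "REQUIRED_COLUMNS",
    "CREATININE_COLUMNS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "read_cohort",
    "write_cohort",
]

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "BLQ")
CREATININE_COLUMNS = ("SCR_UMOLL", "SCR_MGDL")
COVARIATE_COLUMNS = ("AGE_YR", "WT_KG", "HT_M", "GA_WK")


class DatasetValidationError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("dataset validation failed:\n  - " + "\n  - ".join(self.problems))


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a longitudinal dataset; returns it unchanged or raises.

    Checks: required columns present; exactly one unit-suffixed creatinine
    column; non-negative, per-subject non-decreasing times; every observation
    preceded by at least one dose for its subject; DV present iff MDV == 0.
    """
    problems = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing required columns: {missing}")
    scr = [c for c in CREATININE_COLUMNS if c in df.columns]
    bare = [c for c in df.columns if c.upper() in ("SCR", "CREATININE", "CR")]
    if bare:
        problems.append(
            f"creatinine column(s) {bare} lack a unit suffix; "
            "use SCR_UMOLL or SCR_MGDL")
    if not scr and not bare:
        problems.append("no creatinine column (SCR_UMOLL or SCR_MGDL)")
    elif len(scr) > 1:
        problems.append(f"multiple creatinine columns: {scr}")
    for c in COVARIATE_COLUMNS:
        if c not in df.columns:
            problems.append(f"missing covariate column {c}")
    if problems:
        raise DatasetValidationError(problems)

    if (df["TIME"] < 0).any():
        problems.append("negative TIME values")
    for sid, sub in df.groupby("ID", sort=False):
        t = sub["TIME"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            problems.append(f"subject {sid}: TIME not non-decreasing")
        n_doses = (sub["EVID"] == 1).cumsum()
        if ((sub["EVID"] == 0) & (n_doses == 0)).any():
            problems.append(f"subject {sid}: observation row before any dose row")
    obs = df[df["EVID"] == 0]
    bad_dv = obs[(obs["MDV"] == 0) & ~np.isfinite(obs["DV"].to_numpy(float))]
    if len(bad_dv):
        problems.append(f"{len(bad_dv)} observation row(s) with MDV=0 but missing DV")
    if problems:
        raise DatasetValidationError(problems)
    return df


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a longitudinal dataset CSV."""
    df = pd.read_csv(path)
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Validate and write a longitudinal dataset CSV (round-trip safe)."""
    validate_dataset(df)
    df.to_csv(path, index=False)


_COHORT_COLUMNS = ("id", "age_yr", "wt_kg", "ht_m", "scr_umoll", "ga_wk",
                   "egfr_mlmin", "age_group")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    missing = [c for c in _COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DatasetValidationError([f"cohort table missing columns: {missing}"])
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DatasetValidationError([f"cohort table missing columns: {missing}"])
    return cohort
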