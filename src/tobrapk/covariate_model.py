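"""Covariate model for typical clearance and volume.

Typical clearance combines three multiplicative effects on the reference
value (6.17 L/h for a mature 70 kg child with eGFR 127.3 mL/min):

* allometric weight scaling, (WT/70)^0.663;
* renal maturation, a Hill function of post-menstrual age with half-time
  47.7 weeks and coefficient 3.4 (GFR maturation parameters);
* renal function, (eGFR/127.3)^0.4 with eGFR from the modified (bedside)
  Schwartz equation, 41.3 * height(m) / creatinine(mg/dL).

Typical volume scales allometrically only: 15.5 * (WT/70)^0.744.

All functions accept scalars or numpy arrays and are the single source of
truth for the dosing calculator, the target-attainment simulator, and the
mixed-effects estimator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .pk_core import PopulationParameters

__all__ = [
    "PatientCovariates",
    "AgeGroup",
    "CovariateError",
    "UMOL_PER_MGDL",
    "creatinine_mgdl",
    "pma_weeks",
    "maturation",
    "egfr_schwartz",
    "typical_cl",
    "typical_v",
]

#: micromol/L of creatinine per mg/dL (molar mass 113.12 g/mol)
UMOL_PER_MGDL = 88.4

_SUPPORTED_AGE_MAX = 19.3  # years; oldest age the model was built on


class CovariateError(ValueError):
    """Raised for covariates outside the model's domain or with missing units."""


class AgeGroup(str, enum.Enum):
    """Age strata used for reporting: [0, 2), [2, 12], (12, ...]."""

    UNDER_2 = "<2"
    FROM_2_TO_12 = "2-12"
    OVER_12 = ">12"

    @classmethod
    def of(cls, age_years: float) -> "AgeGroup":
        if age_years < 0:
            raise CovariateError("age must be non-negative")
        if age_years < 2:
            return cls.UNDER_2
        if age_years <= 12:
            return cls.FROM_2_TO_12
        return cls.OVER_12


@dataclass(frozen=True)
class PatientCovariates:
    """Covariates driving the clearance/volume model.

    ``serum_creatinine`` must carry an explicit unit ('umol/L' or 'mg/dL');
    silent unit guessing is forbidden.  Gestational age defaults to 40 weeks
    (term birth) when unknown.  ``sex`` is carried for bookkeeping only; it is
    not part of the model.
    """

    age: float                    # years
    weight: float                 # kg
    height: float                 # m
    serum_creatinine: float
    creatinine_unit: str          # 'umol/L' | 'mg/dL'
    gestational_age: float = 40.0  # weeks
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.age < 0 or self.age > _SUPPORTED_AGE_MAX:
            raise CovariateError(
                f"age {self.age} outside supported range [0, {_SUPPORTED_AGE_MAX}] years")
        if self.weight <= 0 or self.height <= 0 or self.serum_creatinine <= 0:
            raise CovariateError("weight, height and creatinine must be positive")
        if not 22 <= self.gestational_age <= 44:
            raise CovariateError("gestational age must lie in [22, 44] weeks")
        creatinine_mgdl(self.serum_creatinine, self.creatinine_unit)  # unit check

    @property
    def age_group(self) -> AgeGroup:
        return AgeGroup.of(self.age)


def creatinine_mgdl(value, unit: str):
    """Convert serum creatinine to mg/dL; the unit tag is mandatory."""
    if unit is None:
        raise CovariateError("creatinine unit missing: specify 'umol/L' or 'mg/dL'")
    u = unit.strip().lower().replace("µ", "u")
    if u in ("umol/l", "umol_l", "umoll"):
        return np.asarray(value, dtype=float) / UMOL_PER_MGDL
    if u in ("mg/dl", "mg_dl", "mgdl"):
        return np.asarray(value, dtype=float) * 1.0
    raise CovariateError(f"unrecognized creatinine unit {unit!r}")


def pma_weeks(age_years, gestational_age_weeks=40.0):
    """Post-menstrual age in weeks: age*52 + gestational age."""
    age_years = np.asarray(age_years, dtype=float)
    if np.any(age_years < 0):
        raise CovariateError("age must be non-negative")
    out = age_years * 52.0 + np.asarray(gestational_age_weeks, dtype=float)
    return float(out) if out.ndim == 0 else out


def maturation(pma, hill: float = 3.4, tm50: float = 47.7):
    """Renal maturation fraction: pma^hill / (tm50^hill + pma^hill), in (0, 1)."""
    pma = np.asarray(pma, dtype=float)
    if np.any(pma <= 0):
        raise CovariateError("post-menstrual age must be positive")
    # evaluate via the ratio form for numerical robustness at large pma
    ratio = (tm50 / pma) ** hill
    out = 1.0 / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def egfr_schwartz(height_m, serum_creatinine, unit: str):
    """Modified Schwartz eGFR, mL/min: 41.3 * height(m) / creatinine(mg/dL)."""
    height_m = np.asarray(height_m, dtype=float)
    if np.any(height_m <= 0):
        raise CovariateError("height must be positive")
    cr = creatinine_mgdl(serum_creatinine, unit)
    if np.any(np.asarray(cr) <= 0):
        raise CovariateError("creatinine must be positive")
    out = 41.3 * height_m / cr
    return float(out) if out.ndim == 0 else out


def typical_cl(cov: PatientCovariates, pop: PopulationParameters | None = None) -> float:
    """Typical (covariate-predicted) clearance in L/h for one patient."""
    pop = pop or PopulationParameters()
    egfr = egfr_schwartz(cov.height, cov.serum_creatinine, cov.creatinine_unit)
    return typical_cl_arrays(cov.age, cov.weight, egfr, pop,
                             gestational_age=cov.gestational_age)


def typical_cl_arrays(age, weight, egfr, pop: PopulationParameters,
                      gestational_age=40.0):
    """Vectorized typical clearance from age (y), weight (kg), eGFR (mL/min)."""
    weight = np.asarray(weight, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    if np.any(weight <= 0) or np.any(egfr <= 0):
        raise CovariateError("weight and eGFR must be positive")
    frac = maturation(pma_weeks(age, gestational_age), pop.hill, pop.tm50)
    out = (pop.theta_CL * frac
           * (weight / pop.ref_WT) ** pop.exp_WT_CL
           * (egfr / pop.ref_eGFR) ** pop.exp_eGFR_CL)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def typical_v(cov_or_weight, pop: PopulationParameters | None = None):
    """Typical volume of distribution in L: theta_V * (WT/70)^0.744."""
    pop = pop or PopulationParameters()
    weight = (cov_or_weight.weight if isinstance(cov_or_weight, PatientCovariates)
              else cov_or_weight)
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise CovariateError("weight must be positive")
    out = pop.theta_V * (weight / pop.ref_WT) ** pop.exp_WT_V
    return float(out) if out.ndim == 0 else out
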