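"""Synthetic pediatric cohorts and simulated TDM concentration datasets.

The study population this emulates is children with cystic fibrosis aged
0.1–19.3 years with age-appropriate anthropometry and age-related normal
serum creatinine.  The generator draws, per virtual patient:

* age uniform within its age group ([0.1, 2), [2, 12], (12, 19.3]);
* weight and height around sex-averaged pediatric growth-reference medians
  (piecewise-linear in age) with lognormal inter-child variability
  (CV 12% weight, 4% height), deviates truncated at +/-3 SD;
* serum creatinine around an age-dependent normal median (micromol/L, rising
  from ~20 in infancy to ~60 in adolescence) with 20% lognormal CV truncated
  at +/-2 SD, i.e. within the age-related normal band;
* gestational age fixed at 40 weeks (term) unless configured otherwise.

``simulate_tdm`` then inverts the estimation model: it draws lognormal
between-subject random effects, evaluates the structural infusion model at
therapeutic-drug-monitoring sampling times (defaults: one draw 1-2 h and one
4-8 h after the start of the infusion, on configurable dose occasions), adds
combined additive+proportional residual error, and censors observations below
the 0.6 mg/L quantification limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariate_model as cm
from .dosing import DosingPolicy, optimal_dose, standard_dose
from .pk_core import PopulationParameters, IndividualParameters, DoseRegimen, concentration

__all__ = [
    "CohortSpec",
    "TDMDesign",
    "generate_cohort",
    "simulate_tdm",
    "censor_blq",
    "DEFAULT_AGE_RANGES",
]

DEFAULT_AGE_RANGES = {"<2": (0.1, 2.0), "2-12": (2.0, 12.0), ">12": (12.0, 19.3)}

# Sex-averaged growth-reference medians, piecewise-linear in age.
_GROWTH_AGE = np.array(
    [0.1, 0.25, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
     11, 12, 13, 14, 15, 16, 17, 18, 19.3])
_GROWTH_WT = np.array(
    [4.5, 6.0, 7.5, 9.5, 12.2, 14.3, 16.3, 18.3, 20.5, 23.0, 25.8, 29.0, 32.5,
     36.5, 41.0, 46.0, 51.0, 55.0, 58.0, 60.0, 62.0, 63.0])   # kg
_GROWTH_HT = np.array(
    [0.55, 0.60, 0.66, 0.75, 0.87, 0.96, 1.03, 1.10, 1.16, 1.22, 1.28, 1.33, 1.38,
     1.44, 1.50, 1.57, 1.63, 1.67, 1.70, 1.72, 1.73, 1.74])   # m

# Age-related normal serum creatinine medians (micromol/L), piecewise-linear.
_SCR_AGE = np.array([0.1, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16, 19.3])
_SCR_MED = np.array([22, 20, 20, 24, 30, 34, 38, 44, 50, 55, 58, 60])


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a virtual cohort, one count per age group."""

    n_per_group: dict = field(
        default_factory=lambda: {"<2": 1000, "2-12": 1000, ">12": 1000})
    age_ranges: dict = field(default_factory=lambda: dict(DEFAULT_AGE_RANGES))
    seed: int = 0
    weight_cv: float = 0.12
    height_cv: float = 0.04
    creatinine_cv: float = 0.20
    creatinine_trunc_sd: float = 2.0   # normal-band truncation of the Cr deviate
    anthro_trunc_sd: float = 3.0
    gestational_age: float = 40.0


@dataclass(frozen=True)
class TDMDesign:
    """TDM sampling design: one draw per window per sampled dose occasion."""

    windows: tuple = ((1.0, 2.0), (4.0, 8.0))  # h after infusion start
    occasions: tuple = (1, 3, 5)               # 1-based dose numbers sampled
    lloq: float = 0.6                          # mg/L

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        for lo, hi in self.windows:
            if not 0 <= lo < hi:
                raise ValueError("sampling window must satisfy 0 <= lo < hi")
        if min(self.occasions, default=1) < 1:
            raise ValueError("occasions are 1-based dose numbers")


def _lognormal_factor(rng, cv, n, trunc_sd):
    sd = np.sqrt(np.log1p(cv ** 2))
    z = rng.normal(0.0, 1.0, n)
    z = np.clip(z, -trunc_sd, trunc_sd)
    return np.exp(sd * z)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a virtual cohort table (one row per patient).

    Columns carry explicit units: ``age_yr, wt_kg, ht_m, scr_umoll, ga_wk,
    egfr_mlmin, age_group``.  Same spec (including seed) gives an identical
    table.
    """
    if not spec.n_per_group:
        raise ValueError("n_per_group is empty")
    frames = []
    next_id = 1
    for gi, (group, n) in enumerate(sorted(spec.n_per_group.items())):
        if n == 0:
            continue
        if n < 0:
            raise ValueError("group sizes must be non-negative")
        lo, hi = spec.age_ranges[group]
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, gi]))
        age = rng.uniform(lo, hi, n)
        wt = np.interp(age, _GROWTH_AGE, _GROWTH_WT) * _lognormal_factor(
            rng, spec.weight_cv, n, spec.anthro_trunc_sd)
        ht = np.interp(age, _GROWTH_AGE, _GROWTH_HT) * _lognormal_factor(
            rng, spec.height_cv, n, spec.anthro_trunc_sd)
        scr = np.interp(age, _SCR_AGE, _SCR_MED) * _lognormal_factor(
            rng, spec.creatinine_cv, n, spec.creatinine_trunc_sd)
        frames.append(pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "age_yr": age,
            "wt_kg": wt,
            "ht_m": ht,
            "scr_umoll": scr,
            "ga_wk": np.full(n, spec.gestational_age),
            "age_group": group,
        }))
        next_id += n
    if not frames:
        return pd.DataFrame(columns=["id", "age_yr", "wt_kg", "ht_m", "scr_umoll",
                                     "ga_wk", "egfr_mlmin", "age_group"])
    cohort = pd.concat(frames, ignore_index=True)
    cohort["egfr_mlmin"] = cm.egfr_schwartz(
        cohort["ht_m"].to_numpy(), cohort["scr_umoll"].to_numpy(), "umol/L")
    return cohort[["id", "age_yr", "wt_kg", "ht_m", "scr_umoll", "ga_wk",
                   "egfr_mlmin", "age_group"]]


def censor_blq(records: pd.DataFrame, lloq: float = 0.6) -> pd.DataFrame:
    """Flag observation rows with DV strictly below ``lloq`` and withhold DV.

    A concentration exactly at the quantification limit is quantifiable and is
    not censored.  Dose rows (EVID != 0) are untouched.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    out = records.copy()
    if out.empty:
        return out
    is_obs = out["EVID"] == 0
    below = is_obs & (out["DV"] < lloq)
    out.loc[below, "BLQ"] = 1
    out.loc[below, "DV"] = np.nan
    out.loc[below, "MDV"] = 1
    return out


def simulate_tdm(cohort: pd.DataFrame, pop: PopulationParameters,
                 design: TDMDesign | None = None,
                 policy: DosingPolicy | None = None,
                 arm: str = "standard",
                 n_days: int | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Simulate a longitudinal NONMEM-style TDM dataset from the full model.

    Each patient receives once-daily infusions (dose set by ``arm``:
    'standard' 10 mg/kg or 'individualized' AUC-targeted with caps) for
    ``n_days`` days (default: enough to cover the last sampled occasion).
    True concentrations use individual CL, V and infusion duration
    (theta_D1*exp(eta)); the dataset's DUR column records the nominal
    0.5 h documented duration, as in routine care.  Residual error is
    y = f*(1+eps_prop) + eps_add; values below the LLOQ are censored.
    """
    design = design or TDMDesign()
    policy = policy or DosingPolicy()
    max_occ = max(design.occasions)
    n_days = n_days or max_occ
    if n_days < max_occ:
        raise ValueError("n_days must cover the last sampled occasion")
    for lo, hi in design.windows:
        if hi > 24.0:
            raise ValueError("sampling window must lie within the 24 h dosing interval")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    rows = []
    pop_typ = pop
    for _, pt in cohort.iterrows():
        tvcl = cm.typical_cl_arrays(pt.age_yr, pt.wt_kg, pt.egfr_mlmin, pop_typ,
                                    gestational_age=pt.ga_wk)
        if arm == "standard":
            rec = standard_dose(pt.wt_kg, policy, typical_CL=tvcl)
        elif arm == "individualized":
            rec = optimal_dose(tvcl, pt.wt_kg, policy)
        else:
            raise ValueError(f"unknown arm {arm!r}")
        eta = rng.normal(0.0, [pop.omega_CL, pop.omega_V, pop.omega_D1])
        ind = IndividualParameters(
            CL=tvcl * np.exp(eta[0]),
            V=cm.typical_v(pt.wt_kg, pop) * np.exp(eta[1]),
            D1=pop.theta_D1 * np.exp(eta[2]),
            eta_CL=eta[0], eta_V=eta[1], eta_D1=eta[2])
        regimen = DoseRegimen(dose=rec.dose, tau=24.0,
                              infusion_duration=ind.D1, n_doses=n_days)
        times = []
        for occ in design.occasions:
            for lo, hi in design.windows:
                times.append(24.0 * (occ - 1) + rng.uniform(lo, hi))
        times = np.sort(np.array(times))
        f = concentration(ind, regimen, times)
        eps_prop = rng.normal(0.0, pop.sigma_prop, times.size)
        eps_add = rng.normal(0.0, pop.sigma_add, times.size)
        y = f * (1.0 + eps_prop) + eps_add
        y = np.clip(y, 0.0, None)
        for d in range(n_days):
            rows.append((pt.id, 24.0 * d, 1, rec.dose, 0.5, np.nan, 1, 0,
                         pt.age_yr, pt.wt_kg, pt.ht_m, pt.scr_umoll, pt.ga_wk))
        for t, obs in zip(times, y):
            rows.append((pt.id, t, 0, np.nan, np.nan, obs, 0, 0,
                         pt.age_yr, pt.wt_kg, pt.ht_m, pt.scr_umoll, pt.ga_wk))
    cols = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "BLQ",
            "AGE_YR", "WT_KG", "HT_M", "SCR_UMOLL", "GA_WK"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False], kind="mergesort")
    df = df.reset_index(drop=True)
    return censor_blq(df, design.lloq)
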