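"""Dose computation: standard weight-based and individualized AUC-targeted dosing.

The individualized rule inverts the steady-state identity AUC24,ss = dose/CL:
dose (mg) = target_auc * typical CL, with the typical clearance predicted from
covariates.  Institutional caps bound the daily dose at min(850 mg, 16 mg/kg).
The standard-of-care comparator is a fixed 10 mg/kg once daily, uncapped by
default (mirroring the simulation arm it reproduces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DosingPolicy", "DoseRecommendation", "optimal_dose", "standard_dose"]


@dataclass(frozen=True)
class DosingPolicy:
    target_auc: float = 95.0      # mg·h/L, individualized-dose target
    cap_abs: float = 850.0        # mg, absolute daily cap
    cap_perkg: float = 16.0       # mg/kg daily cap
    standard_perkg: float = 10.0  # mg/kg, standard-of-care dose
    cap_standard: bool = False    # whether caps also apply to the standard arm
    round_to: float | None = None  # optional rounding increment, mg

    def __post_init__(self) -> None:
        for name in ("target_auc", "cap_abs", "cap_perkg", "standard_perkg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DoseRecommendation:
    dose: float                   # mg per 24 h
    dose_perkg: float             # mg/kg
    cap_applied: str              # 'none' | 'absolute' | 'per-kg'
    predicted_auc: float          # mg·h/L at the typical clearance


def _finish(dose: float, weight: float, cap: str, typical_CL: float,
            policy: DosingPolicy) -> DoseRecommendation:
    if policy.round_to:
        dose = policy.round_to * round(dose / policy.round_to)
    return DoseRecommendation(
        dose=dose,
        dose_perkg=dose / weight,
        cap_applied=cap,
        predicted_auc=dose / typical_CL,
    )


def optimal_dose(typical_CL: float, weight: float,
                 policy: DosingPolicy | None = None) -> DoseRecommendation:
    """AUC-targeted individualized dose: min(target_auc*CL, 850 mg, 16 mg/kg)."""
    policy = policy or DosingPolicy()
    if typical_CL <= 0 or weight <= 0:
        raise ValueError("typical_CL and weight must be strictly positive")
    uncapped = policy.target_auc * typical_CL
    perkg_cap = policy.cap_perkg * weight
    dose = min(uncapped, policy.cap_abs, perkg_cap)
    if dose == uncapped:
        cap = "none"
    elif policy.cap_abs <= perkg_cap:
        cap = "absolute"
    else:
        cap = "per-kg"
    return _finish(dose, weight, cap, typical_CL, policy)


def standard_dose(weight: float, policy: DosingPolicy | None = None,
                  typical_CL: float = np.nan) -> DoseRecommendation:
    """Standard-of-care dose: 10 mg/kg once daily (uncapped unless configured)."""
    policy = policy or DosingPolicy()
    if weight <= 0:
        raise ValueError("weight must be strictly positive")
    dose = policy.standard_perkg * weight
    cap = "none"
    if policy.cap_standard:
        perkg_cap = policy.cap_perkg * weight
        capped = min(dose, policy.cap_abs, perkg_cap)
        if capped < dose:
            cap = "absolute" if policy.cap_abs <= perkg_cap else "per-kg"
        dose = capped
    return _finish(dose, weight, cap, typical_CL, policy)
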