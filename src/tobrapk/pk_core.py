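"""One-compartment IV-infusion structural model and population-parameter containers.

The structural model is a one-compartment disposition with zero-order input
(constant-rate infusion of duration D1) and first-order elimination,
parameterized by clearance CL (L/h), volume V (L), and infusion duration
D1 (h).  Between-subject variability is lognormal: an individual's parameter
is the typical value times exp(eta), with eta ~ N(0, omega^2) and a diagonal
omega matrix.  Residual (assay) variability is combined additive plus
proportional, y = f*(1 + eps_prop) + eps_add.

Steady-state exposure over a 24 h interval reduces to the exact identity
AUC24,ss = dose / CL, which is the quantity dosing and target-attainment
simulations operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationParameters",
    "IndividualParameters",
    "DoseRegimen",
    "ConcentrationRecord",
    "InvalidParameterError",
    "concentration",
    "auc24_ss",
    "sample_individual",
]


class InvalidParameterError(ValueError):
    """Raised when a PK parameter violates its positivity/range contract."""


@dataclass(frozen=True)
class PopulationParameters:
    """Final population model estimates.

    Typical (reference) values apply to a 70 kg individual with fully matured
    renal function and an eGFR of 127.3 mL/min.  Omegas are standard
    deviations of the lognormal between-subject random effects; sigma_add
    (mg/L) and sigma_prop (fraction) parameterize the combined residual error.
    """

    theta_CL: float = 6.17        # typical clearance, L/h
    theta_V: float = 15.5         # typical volume of distribution, L
    theta_D1: float = 0.801       # fitted typical infusion duration, h
    exp_WT_CL: float = 0.663      # allometric weight exponent on CL
    exp_WT_V: float = 0.744       # allometric weight exponent on V
    exp_eGFR_CL: float = 0.4      # eGFR exponent on CL (fixed, not re-estimated)
    hill: float = 3.4             # maturation Hill coefficient
    tm50: float = 47.7            # maturation half-time, weeks PMA
    ref_WT: float = 70.0          # reference weight, kg
    ref_eGFR: float = 127.3       # reference eGFR, mL/min
    omega_CL: float = 0.170
    omega_V: float = 0.173
    omega_D1: float = 0.404
    sigma_add: float = 0.173      # additive residual SD, mg/L
    sigma_prop: float = 0.103     # proportional residual SD, fraction

    def __post_init__(self) -> None:
        for name in ("theta_CL", "theta_V", "theta_D1", "exp_WT_CL", "exp_WT_V",
                     "exp_eGFR_CL", "hill", "tm50", "ref_WT", "ref_eGFR"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("omega_CL", "omega_V", "omega_D1", "sigma_add", "sigma_prop"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualParameters:
    """Realized per-subject parameters: typical value times exp(eta)."""

    CL: float
    V: float
    D1: float
    eta_CL: float = 0.0
    eta_V: float = 0.0
    eta_D1: float = 0.0

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V > 0 and self.D1 > 0):
            raise InvalidParameterError("CL, V and D1 must be strictly positive")


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated IV-infusion regimen.

    ``n_doses=None`` selects steady-state mode: the profile is the periodic
    limit of once-per-``tau`` dosing and ``t`` is interpreted modulo ``tau``.
    """

    dose: float                   # mg per administration
    tau: float = 24.0             # dosing interval, h
    infusion_duration: float = 0.5  # h
    n_doses: int | None = None    # None -> steady state

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidParameterError("dose must be non-negative")
        if not 0 < self.infusion_duration <= self.tau:
            raise InvalidParameterError("need 0 < infusion_duration <= tau")
        if self.n_doses is not None and self.n_doses < 1:
            raise InvalidParameterError("n_doses must be >= 1 (or None)")


@dataclass(frozen=True)
class ConcentrationRecord:
    """A single observed (or censored) concentration."""

    time: float                   # h since first dose
    concentration: float | None   # mg/L; None when censored
    blq: bool = False
    interval_index: int = 0       # dose interval the sample falls in

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidParameterError("time must be non-negative")


def _single_dose_profile(t, dose, d1, cl, v):
    """Concentration after one infusion started at t=0 (vectorized, 0 for t<0)."""
    t = np.asarray(t, dtype=float)
    k = cl / v
    r0 = dose / d1  # mg/h
    during = (r0 / cl) * -np.expm1(-k * np.clip(t, 0.0, d1))
    after = (r0 / cl) * -np.expm1(-k * d1) * np.exp(-k * np.clip(t - d1, 0.0, None))
    out = np.where(t < d1, during, after)
    return np.where(t < 0, 0.0, out)


def concentration(params: IndividualParameters, regimen: DoseRegimen, t):
    """Serum concentration (mg/L) at time(s) ``t`` hours after the first dose.

    Finite regimens superpose the single-dose solution over all administered
    doses; steady-state mode applies the standard accumulation factor
    1/(1 - exp(-k*tau)) to the within-interval profile.
    """
    if not (params.CL > 0 and params.V > 0):
        raise InvalidParameterError("CL and V must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be non-negative")
    dose, tau, d1 = regimen.dose, regimen.tau, regimen.infusion_duration
    if dose == 0:
        return np.zeros_like(t) if t.ndim else 0.0
    cl, v = params.CL, params.V
    if regimen.n_doses is None:
        k = cl / v
        tw = np.mod(t, tau)
        acc = np.exp(-k * tau) / -np.expm1(-k * tau)
        base = _single_dose_profile(tw, dose, d1, cl, v)
        # periodic tail from all previous doses, itself periodic with period tau
        tail = (dose / d1 / cl) * -np.expm1(-k * d1) * np.exp(-k * (tw - d1)) * acc
        out = base + tail
    else:
        starts = tau * np.arange(regimen.n_doses)
        out = _single_dose_profile(t[..., None] - starts, dose, d1, cl, v).sum(axis=-1)
    return float(out) if t.ndim == 0 else out


def auc24_ss(dose: float, CL: float) -> float:
    """Steady-state 24 h area under the curve, mg·h/L: dose / CL."""
    if CL <= 0:
        raise InvalidParameterError("CL must be strictly positive")
    if dose < 0:
        raise InvalidParameterError("dose must be non-negative")
    return dose / CL


def sample_individual(pop: PopulationParameters, typical_CL: float,
                      typical_V: float, rng) -> IndividualParameters:
    """Draw one individual from the population distribution.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.  Etas are
    independent zero-mean normals with SDs (omega_CL, omega_V, omega_D1);
    parameters are formed multiplicatively around the supplied typical values
    (and ``pop.theta_D1`` for the infusion duration).
    """
    if not (typical_CL > 0 and typical_V > 0):
        raise InvalidParameterError("typical values must be strictly positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eta_cl = rng.normal(0.0, pop.omega_CL)
    eta_v = rng.normal(0.0, pop.omega_V)
    eta_d1 = rng.normal(0.0, pop.omega_D1)
    return IndividualParameters(
        CL=typical_CL * np.exp(eta_cl),
        V=typical_V * np.exp(eta_v),
        D1=pop.theta_D1 * np.exp(eta_d1),
        eta_CL=eta_cl, eta_V=eta_v, eta_D1=eta_d1,
    )
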