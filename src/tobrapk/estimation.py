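"""Nonlinear mixed-effects estimation of the population PK model.

The marginal likelihood of each subject's concentration data, integrated over
the lognormal random effects (eta_CL, eta_V, eta_D1), is approximated by a
Laplace expansion around the conditional mode with Gauss-Newton curvature —
the same family of conditional-linearization approximations as FOCE with
interaction.  Writing, for subject i with observations y_ij and model
predictions f_ij(eta),

    h_i(eta) = sum_j [ (y_ij - f_ij)^2 / g_ij + ln(2 pi g_ij) ]
               + eta' Omega^-1 eta + ln det(2 pi Omega),
    g_ij = sigma_add^2 + sigma_prop^2 f_ij^2,

the contribution to the objective function (OFV, -2 log-likelihood up to no
additive constant) is

    OFV_i = h_i(eta*) + ln det( J' G^-1 J + Omega^-1 ) - q ln(2 pi),

with eta* the minimizer of h_i, J the Jacobian of f with respect to the q
active random effects at eta*, and G = diag(g).  With all omegas zero the
etas are pinned and OFV reduces to the exact weighted least-squares deviance
sum_j [(y-f)^2/g + ln g] + n ln(2 pi).

Fixed effects, omegas and sigmas are estimated by minimizing the OFV with a
staged scheme — a quasi-gradient stage (L-BFGS-B on finite differences)
followed by derivative-free direction-set (Powell) sweeps — with positivity
enforced through log transformation of scale and variance parameters.
Covariate selection follows the forward stepwise likelihood-ratio procedure:
a candidate enters when it drops the OFV by more than the chi-squared
critical value (3.84 for one extra parameter, p < 0.05).

BLQ observations are handled by the M6 rule before fitting: within each dose
interval, the first observation of each consecutive run of BLQ values is
imputed at half the quantification limit (0.3 mg/L) and retained; subsequent
BLQ values in the run are discarded.  A quantifiable observation terminates
the run, so a later BLQ starts a new run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariate_model import egfr_schwartz, maturation, pma_weeks
from .pk_core import ConcentrationRecord

__all__ = [
    "EstimationError",
    "EstimationSettings",
    "CovariateCandidate",
    "FitResult",
    "LRTDecision",
    "SelectionStep",
    "SelectionResult",
    "DEFAULT_INITIALS",
    "preprocess_m6",
    "assign_intervals",
    "objective_function",
    "fit",
    "lrt_covariate_step",
    "screen_candidates",
    "forward_selection",
]


class EstimationError(RuntimeError):
    """Raised when the likelihood is undefined or the dataset is unusable."""


#: literature-plausible starting values for the optimizer
DEFAULT_INITIALS = {
    "theta_cl": 5.0, "theta_v": 20.0, "theta_d1": 0.5,
    "omega_cl": 0.2, "omega_v": 0.2, "omega_d1": 0.2,
    "sigma_add": 0.2, "sigma_prop": 0.1,
    "exp_wt_cl": 0.663, "exp_wt_v": 0.744, "exp_egfr_cl": 0.4,
}

_DEFAULT_FREE = ("theta_cl", "theta_v", "theta_d1",
                 "omega_cl", "omega_v", "omega_d1", "sigma_add", "sigma_prop")

_LOG_SCALE = {"theta_cl", "theta_v", "theta_d1",
              "omega_cl", "omega_v", "omega_d1", "sigma_add", "sigma_prop"}


@dataclass(frozen=True)
class CovariateCandidate:
    """One covariate-parameter relation tested in forward selection.

    ``form='power'`` multiplies the parameter by (x / median(x))^beta for a
    continuous covariate scaled to the population median; ``form='exp'``
    multiplies by exp(beta * x), the natural choice for a binary flag.
    ``key`` names a per-subject quantity: a dataset column, or one of the
    built-ins 'egfr', 'wt'.
    """

    target: str                   # 'cl' | 'v'
    name: str
    key: str
    form: str = "power"
    init: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in ("cl", "v"):
            raise ValueError("target must be 'cl' or 'v'")
        if self.form not in ("power", "exp"):
            raise ValueError("form must be 'power' or 'exp'")

    @property
    def param(self) -> str:
        return f"beta_{self.name}"


def egfr_candidate() -> CovariateCandidate:
    """The renal-function candidate: power of median-scaled eGFR on clearance."""
    return CovariateCandidate(target="cl", name="egfr", key="egfr", form="power")


@dataclass(frozen=True)
class EstimationSettings:
    """Model structure, initial estimates and optimizer controls."""

    method: str = "laplace"
    init: dict = field(default_factory=dict)     # overrides of DEFAULT_INITIALS
    free: tuple = _DEFAULT_FREE
    include_egfr: bool = True                    # (eGFR/127.3)^exp_egfr_cl on CL
    candidates: tuple = ()                       # applied CovariateCandidates
    hill: float = 3.4
    tm50: float = 47.7
    ref_wt: float = 70.0
    ref_egfr: float = 127.3
    inner_maxiter: int = 15
    inner_tol: float = 1e-8
    outer_maxfev_grad: int = 250   # budget of the quasi-gradient stage
    outer_maxfev_sweep: int = 700  # budget of each direction-set sweep
    outer_max_sweeps: int = 1
    outer_ftol: float = 1e-9   # relative
    outer_xtol: float = 1e-5
    outer_eps: float = 1e-5    # finite-difference step, transformed scale
    outer_polish: bool = True  # follow gradient stage with direction-set sweeps

    def initials(self) -> dict:
        params = dict(DEFAULT_INITIALS)
        params.update(self.init)
        for cand in self.candidates:
            params.setdefault(cand.param, cand.init)
        missing = [p for p in self.free if p not in params]
        if missing:
            raise EstimationError(f"no initial estimate for free parameter(s) {missing}")
        bad = [p for p in self.free if p in _LOG_SCALE and params[p] <= 0]
        if bad:
            raise EstimationError(f"initial estimates must be positive: {bad}")
        if not self.free:
            raise EstimationError("at least one parameter must be free")
        return params

    def with_(self, **kwargs) -> "EstimationSettings":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FitResult:
    estimates: dict
    ofv: float
    converged: bool
    n_evals: int
    message: str = ""
    eta_modes: np.ndarray | None = None   # (n_subjects, 3) conditional modes
    se: dict | None = None


@dataclass(frozen=True)
class LRTDecision:
    significant: bool
    p_value: float
    drop: float
    df: int
    warning: str | None = None


@dataclass(frozen=True)
class SelectionStep:
    candidate: str
    drop: float
    p_value: float
    accepted: bool
    note: str = ""


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple
    steps: tuple
    base_fit: FitResult
    final_fit: FitResult


# ---------------------------------------------------------------------------
# M6 BLQ preprocessing
# ---------------------------------------------------------------------------

def assign_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Attach a 0-based dose-interval index to every row of a dataset.

    The interval of a row is the count of dose events (EVID==1) of the same
    subject at or before its time, minus one.  Observations preceding any
    dose raise, since BLQ sequencing is defined per dose.
    """
    out = df.copy()
    idx = np.empty(len(out), dtype=int)
    for _, sub in out.groupby("ID", sort=False):
        n_doses = (sub["EVID"] == 1).cumsum()
        if ((sub["EVID"] == 0) & (n_doses == 0)).any():
            raise EstimationError(
                f"subject {sub['ID'].iloc[0]}: observation before any dose; "
                "cannot assign a dose interval")
        idx[sub.index.to_numpy()] = n_doses.to_numpy() - 1
    out["INTERVAL"] = idx
    return out


def _m6_keep_mask(blq_flags: Sequence[bool]) -> list[str]:
    """Per record: 'keep' | 'impute' | 'drop' under the M6 run rule."""
    actions, in_run = [], False
    for is_blq in blq_flags:
        if not is_blq:
            actions.append("keep")
            in_run = False
        elif not in_run:
            actions.append("impute")
            in_run = True
        else:
            actions.append("drop")
    return actions


def preprocess_m6(records, lloq: float = 0.6):
    """Apply the M6 below-quantification rule.

    Within each dose interval, the first BLQ value of each consecutive run is
    replaced by half the quantification limit (lloq/2) and kept as an
    observation; subsequent BLQ values in the run are excluded.  Non-BLQ
    records are never modified and the record count never increases.

    Accepts either a dataset DataFrame (columns ID/TIME/EVID/DV/MDV/BLQ; an
    INTERVAL column is derived from dose events if absent) or a sequence of
    :class:`ConcentrationRecord` with ``interval_index`` set.
    """
    half = lloq / 2.0
    if isinstance(records, pd.DataFrame):
        df = records if "INTERVAL" in records.columns else assign_intervals(records)
        df = df.copy().reset_index(drop=True)
        obs = df["EVID"] == 0
        drop_rows = []
        for (_, _), sub in df[obs].groupby(["ID", "INTERVAL"], sort=False):
            actions = _m6_keep_mask((sub["BLQ"] == 1).tolist())
            for row, act in zip(sub.index, actions):
                if act == "impute":
                    df.loc[row, ["DV", "MDV", "BLQ"]] = [half, 0, 1]
                elif act == "drop":
                    drop_rows.append(row)
        return df.drop(index=drop_rows).reset_index(drop=True)
    # sequence of ConcentrationRecord
    recs = list(records)
    out = []
    by_interval: dict[int, list[ConcentrationRecord]] = {}
    for r in recs:
        by_interval.setdefault(r.interval_index, []).append(r)
    for _, group in sorted(by_interval.items()):
        actions = _m6_keep_mask([r.blq for r in group])
        for r, act in zip(group, actions):
            if act == "keep":
                out.append(r)
            elif act == "impute":
                out.append(ConcentrationRecord(time=r.time, concentration=half,
                                               blq=True,
                                               interval_index=r.interval_index))
    out.sort(key=lambda r: r.time)
    return out


# ---------------------------------------------------------------------------
# dataset flattening
# ---------------------------------------------------------------------------

class _FitData:
    """Dataset flattened into numpy arrays for fast repeated OFV evaluation."""

    def __init__(self, df: pd.DataFrame, settings: EstimationSettings):
        need = {"ID", "TIME", "EVID", "AMT", "DV", "MDV"}
        missing = need - set(df.columns)
        if missing:
            raise EstimationError(f"dataset lacks required columns: {sorted(missing)}")
        ids = pd.unique(df["ID"])
        self.ids = ids
        self.n_subj = len(ids)
        id_index = {sid: i for i, sid in enumerate(ids)}

        obs = df[(df["EVID"] == 0) & (df["MDV"] == 0)]
        if obs.empty:
            raise EstimationError("dataset has no usable observations")
        self.t_obs = obs["TIME"].to_numpy(float)
        self.y = obs["DV"].to_numpy(float)
        self.obs_subj = obs["ID"].map(id_index).to_numpy(int)
        self.obs_label = list(zip(obs["ID"], obs["TIME"]))
        self.n_obs = len(obs)

        doses = df[df["EVID"] == 1]
        pair_obs, pair_subj, pair_dt, pair_amt = [], [], [], []
        dose_by_subj = {i: [] for i in range(self.n_subj)}
        for sid, t, amt in zip(doses["ID"], doses["TIME"], doses["AMT"]):
            dose_by_subj[id_index[sid]].append((float(t), float(amt)))
        for j in range(self.n_obs):
            i = self.obs_subj[j]
            for td, amt in dose_by_subj[i]:
                if td < self.t_obs[j]:
                    pair_obs.append(j)
                    pair_subj.append(i)
                    pair_dt.append(self.t_obs[j] - td)
                    pair_amt.append(amt)
        if not pair_obs:
            raise EstimationError("no observation follows a dose")
        self.pair_obs = np.array(pair_obs, int)
        self.pair_subj = np.array(pair_subj, int)
        self.pair_dt = np.array(pair_dt, float)
        self.pair_amt = np.array(pair_amt, float)

        # per-subject covariates from each subject's first row
        first = df.groupby("ID", sort=False).first().loc[ids]
        self.cov: dict[str, np.ndarray] = {}
        if {"WT_KG"} <= set(df.columns):
            wt = first["WT_KG"].to_numpy(float)
            self.cov["wt"] = wt
            self.wt_ratio = wt / settings.ref_wt
        else:
            self.wt_ratio = np.ones(self.n_subj)
        if {"AGE_YR"} <= set(df.columns):
            ga = first["GA_WK"].to_numpy(float) if "GA_WK" in df.columns else 40.0
            self.mat = maturation(pma_weeks(first["AGE_YR"].to_numpy(float), ga),
                                  settings.hill, settings.tm50)
        else:
            self.mat = np.ones(self.n_subj)
        scr_cols = [c for c in df.columns if c.startswith("SCR_")]
        if "HT_M" in df.columns and scr_cols:
            unit = {"SCR_UMOLL": "umol/L", "SCR_MGDL": "mg/dL"}[scr_cols[0]]
            egfr = egfr_schwartz(first["HT_M"].to_numpy(float),
                                 first[scr_cols[0]].to_numpy(float), unit)
            self.cov["egfr"] = egfr
            self.egfr_ratio = egfr / settings.ref_egfr
        else:
            self.egfr_ratio = np.ones(self.n_subj)
        for col in df.columns:
            if col not in self.cov and col not in {
                    "ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "BLQ",
                    "INTERVAL"} and pd.api.types.is_numeric_dtype(df[col]):
                self.cov[col] = first[col].to_numpy(float)

    def candidate_values(self, cand: CovariateCandidate) -> np.ndarray:
        if cand.key not in self.cov:
            raise EstimationError(f"candidate covariate {cand.key!r} not in dataset")
        x = self.cov[cand.key]
        if cand.form == "power":
            med = np.median(x)
            if med <= 0 or np.any(x <= 0):
                raise EstimationError(
                    f"power-form candidate {cand.name!r} needs positive values")
            return x / med
        return x


# ---------------------------------------------------------------------------
# Laplace objective
# ---------------------------------------------------------------------------

_ACTIVE_OMEGA_FLOOR = 1e-8


def _typical_values(data: _FitData, params: dict, settings: EstimationSettings):
    tvcl = (params["theta_cl"] * data.mat
            * data.wt_ratio ** params["exp_wt_cl"])
    if settings.include_egfr:
        tvcl = tvcl * data.egfr_ratio ** params["exp_egfr_cl"]
    tvv = params["theta_v"] * data.wt_ratio ** params["exp_wt_v"]
    for cand in settings.candidates:
        x = data.candidate_values(cand)
        beta = params[cand.param]
        mult = x ** beta if cand.form == "power" else np.exp(beta * x)
        if cand.target == "cl":
            tvcl = tvcl * mult
        else:
            tvv = tvv * mult
    return tvcl, tvv


def _predict(data: _FitData, cl, v, d1):
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        k = cl / v
        kp = k[data.pair_subj]
        d1p = d1[data.pair_subj]
        r0cl = data.pair_amt / (d1p * cl[data.pair_subj])
        dt = data.pair_dt
        during = r0cl * -np.expm1(-kp * np.minimum(dt, d1p))
        after = (r0cl * -np.expm1(-kp * d1p)
                 * np.exp(-kp * np.clip(dt - d1p, 0.0, None)))
        c = np.where(dt < d1p, during, after)
    if not np.all(np.isfinite(c)):
        raise EstimationError("non-finite concentration prediction "
                              "(extreme parameter or random-effect value)")
    return np.bincount(data.pair_obs, weights=c, minlength=data.n_obs)


def _predict_with_jac(data: _FitData, cl, v, d1):
    """Prediction and its exact Jacobian w.r.t. (ln CL, ln V, ln D1).

    Analytic differentiation of the infusion superposition: for each
    dose-observation pair, c = A(1-E) during the infusion and
    c = A(1-Ed)Ep after it, with A = amt/(D1*CL), E = exp(-k*dt),
    Ed = exp(-k*D1), Ep = exp(-k*(dt-D1)), k = CL/V.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        k = cl / v
        kp = k[data.pair_subj]
        d1p = d1[data.pair_subj]
        A = data.pair_amt / (d1p * cl[data.pair_subj])
        dt = data.pair_dt
        in_inf = dt < d1p
        tE = np.minimum(dt, d1p)
        E = np.exp(-kp * tE)
        c1 = A * (1.0 - E)
        dc1_lncl = -c1 + A * kp * tE * E
        dc1_lnv = -A * kp * tE * E
        dc1_lnd1 = -c1
        te = np.clip(dt - d1p, 0.0, None)
        Ed = np.exp(-kp * d1p)
        Ep = np.exp(-kp * te)
        c2 = A * (1.0 - Ed) * Ep
        dc2_lncl = -c2 + A * Ep * kp * (d1p * Ed - (1.0 - Ed) * te)
        dc2_lnv = A * Ep * kp * (-d1p * Ed + (1.0 - Ed) * te)
        dc2_lnd1 = -c2 + A * kp * d1p * Ep
        c = np.where(in_inf, c1, c2)
        dcl = np.where(in_inf, dc1_lncl, dc2_lncl)
        dv = np.where(in_inf, dc1_lnv, dc2_lnv)
        dd1 = np.where(in_inf, dc1_lnd1, dc2_lnd1)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(dcl))
            and np.all(np.isfinite(dv)) and np.all(np.isfinite(dd1))):
        raise EstimationError("non-finite concentration prediction "
                              "(extreme parameter or random-effect value)")
    f = np.bincount(data.pair_obs, weights=c, minlength=data.n_obs)
    J = np.stack([np.bincount(data.pair_obs, weights=w, minlength=data.n_obs)
                  for w in (dcl, dv, dd1)], axis=1)
    return f, J


def _laplace_ofv(data: _FitData, params: dict, settings: EstimationSettings,
                 eta_warm: np.ndarray | None = None):
    """Return (ofv, eta_modes). Raises EstimationError on undefined likelihood."""
    tvcl, tvv = _typical_values(data, params, settings)
    if np.any(tvcl <= 0) or np.any(tvv <= 0) or params["theta_d1"] <= 0:
        raise EstimationError("non-positive structural parameter")
    th_d1 = params["theta_d1"]
    sa2 = params["sigma_add"] ** 2
    sp2 = params["sigma_prop"] ** 2
    omegas = np.array([params["omega_cl"], params["omega_v"], params["omega_d1"]])
    active = np.flatnonzero(omegas > _ACTIVE_OMEGA_FLOOR)
    q = active.size
    N = data.n_subj

    def f_of(etas):
        etas = np.clip(etas, -15.0, 15.0)
        cl = tvcl * np.exp(etas[:, 0])
        v = tvv * np.exp(etas[:, 1])
        d1 = th_d1 * np.exp(etas[:, 2])
        return _predict(data, cl, v, d1)

    def data_part(f):
        g = sa2 + sp2 * f * f
        if np.any(g <= 0) or not np.all(np.isfinite(g)):
            j = int(np.argmin(g))
            sid, t = data.obs_label[j]
            raise EstimationError(
                f"residual variance not positive at subject {sid}, t={t:.3g} h "
                "(zero prediction with proportional-only error?)")
        r = data.y - f
        lobs = np.bincount(data.obs_subj, weights=r * r / g + np.log(2 * np.pi * g),
                           minlength=N)
        return lobs, g, r

    if q == 0:
        f = f_of(np.zeros((N, 3)))
        lobs, _, _ = data_part(f)
        ofv = float(lobs.sum())
        if not math.isfinite(ofv):
            raise EstimationError("non-finite objective")
        return ofv, np.zeros((N, 3))

    om2 = omegas[active] ** 2
    pen_const = float(np.log(2 * np.pi * om2).sum())

    eta = np.zeros((N, 3)) if eta_warm is None else eta_warm.copy()
    eta[:, [d for d in range(3) if d not in active]] = 0.0

    def h_of(etas):
        f = f_of(etas)
        lobs, g, r = data_part(f)
        pen = (etas[:, active] ** 2 / om2).sum(axis=1) + pen_const
        return lobs + pen, f, g, r

    h, f, g, r = h_of(eta)

    def grad_and_hess(eta, f, g, r):
        etac = np.clip(eta, -15.0, 15.0)
        cl = tvcl * np.exp(etac[:, 0])
        v = tvv * np.exp(etac[:, 1])
        d1 = th_d1 * np.exp(etac[:, 2])
        _, J_full = _predict_with_jac(data, cl, v, d1)
        J = J_full[:, active]
        gp = 2.0 * sp2 * f
        with np.errstate(over="ignore", invalid="ignore"):
            dldf = -2.0 * r / g - r * r * gp / (g * g) + gp / g
        if not np.all(np.isfinite(dldf)):
            raise EstimationError("non-finite inner gradient")
        grad = np.stack(
            [np.bincount(data.obs_subj, weights=dldf * J[:, jdim], minlength=N)
             for jdim in range(q)], axis=1)
        grad += 2.0 * eta[:, active] / om2
        Hh = np.empty((N, q, q))
        for a in range(q):
            for b in range(a, q):
                val = np.bincount(data.obs_subj, weights=J[:, a] * J[:, b] / g,
                                  minlength=N)
                Hh[:, a, b] = val
                Hh[:, b, a] = val
        Hh[:, np.arange(q), np.arange(q)] += 1.0 / om2
        return grad, Hh

    for _ in range(settings.inner_maxiter):
        grad, Hh = grad_and_hess(eta, f, g, r)
        try:
            step = -np.linalg.solve(2.0 * Hh, grad[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular conditional-mode Hessian: {exc}") from exc
        # per-subject backtracking: halve the step where h would increase
        # (tolerance relative to |h| so float round-off never triggers it)
        tol_ls = 1e-9 * np.abs(h) + 1e-12
        alpha = np.ones(N)
        for _ls in range(8):
            trial = eta.copy()
            trial[:, active] = eta[:, active] + alpha[:, None] * step
            h_trial, f_t, g_t, r_t = h_of(trial)
            worse = h_trial > h + tol_ls
            if not worse.any():
                break
            alpha[worse] *= 0.5
        improve = h_trial <= h + tol_ls
        if improve.all():
            eta_next, h_next, f, g, r = trial, h_trial, f_t, g_t, r_t
        else:
            eta_next = eta.copy()
            eta_next[improve] = trial[improve]
            h_next, f, g, r = h_of(eta_next)
        delta_h = float(np.max(np.abs(h - h_next)))
        eta, h = eta_next, h_next
        if delta_h < settings.inner_tol:
            break

    _, Hh = grad_and_hess(eta, f, g, r)
    sign, logdet = np.linalg.slogdet(Hh)
    if np.any(sign <= 0):
        raise EstimationError("conditional-mode curvature not positive definite")
    ofv = float(h.sum() + logdet.sum() - N * q * np.log(2 * np.pi))
    if not math.isfinite(ofv):
        raise EstimationError("non-finite objective")
    return ofv, eta


def _as_param_dict(params) -> dict:
    if isinstance(params, dict):
        return dict(params)
    # PopulationParameters-like object
    return {
        "theta_cl": params.theta_CL, "theta_v": params.theta_V,
        "theta_d1": params.theta_D1,
        "omega_cl": params.omega_CL, "omega_v": params.omega_V,
        "omega_d1": params.omega_D1,
        "sigma_add": params.sigma_add, "sigma_prop": params.sigma_prop,
        "exp_wt_cl": params.exp_WT_CL, "exp_wt_v": params.exp_WT_V,
        "exp_egfr_cl": params.exp_eGFR_CL,
    }


def objective_function(dataset: pd.DataFrame, params,
                       settings: EstimationSettings | None = None) -> float:
    """OFV (-2 approximate marginal log-likelihood) of a dataset at ``params``.

    ``params`` may be a name->value dict or a PopulationParameters instance.
    Rows with MDV==1 are ignored; apply :func:`preprocess_m6` first if BLQ
    observations should contribute.
    """
    settings = settings or EstimationSettings()
    data = dataset if isinstance(dataset, _FitData) else _FitData(dataset, settings)
    full = dict(DEFAULT_INITIALS)
    full.update(_as_param_dict(params))
    ofv, _ = _laplace_ofv(data, full, settings)
    return ofv


# ---------------------------------------------------------------------------
# fitting and covariate selection
# ---------------------------------------------------------------------------

def _pack(params: dict, free) -> np.ndarray:
    return np.array([np.log(params[p]) if p in _LOG_SCALE else params[p]
                     for p in free])


def _unpack(x: np.ndarray, params: dict, free) -> dict:
    out = dict(params)
    for xi, p in zip(x, free):
        out[p] = float(np.exp(xi)) if p in _LOG_SCALE else float(xi)
    return out


def fit(dataset: pd.DataFrame, settings: EstimationSettings | None = None) -> FitResult:
    """Estimate free parameters by minimizing the Laplace OFV.

    Requires at least two subjects with at least one observation each.
    Non-convergence within the function-evaluation budget returns a flagged
    result with the best estimates found rather than raising.
    """
    settings = settings or EstimationSettings()
    data = dataset if isinstance(dataset, _FitData) else _FitData(dataset, settings)
    if data.n_subj < 2:
        raise EstimationError("need at least 2 subjects with observations")
    params0 = settings.initials()
    free = tuple(settings.free)
    bad = 1e10
    x0 = _pack(params0, free)
    # fixed warm-start reference for the inner conditional-mode search: the
    # objective is then a deterministic function of x (no dependence on the
    # evaluation history), which both the finite-difference gradient method
    # and the direction-set line searches require to behave
    state = {"ref": None}

    def refresh_ref(x):
        try:
            _, eta = _laplace_ofv(data, _unpack(x, params0, free),
                                  settings.with_(inner_maxiter=60), eta_warm=None)
            state["ref"] = eta
        except EstimationError:
            state["ref"] = None

    def objective(x):
        # soft trust region keeps line searches off the -inf plateaus of
        # unidentifiable log-variance parameters
        excess = np.abs(x - x0) - 6.0
        if np.any(excess > 0):
            return bad + 1e6 * float(excess[excess > 0].sum())
        params = _unpack(x, params0, free)
        try:
            ofv, _ = _laplace_ofv(data, params, settings, eta_warm=state["ref"])
        except EstimationError:
            return bad
        return ofv

    def final_ofv(x):
        # cold inner start with extra iterations: path-independent, so OFVs
        # of different fits are comparable in likelihood-ratio tests
        return _laplace_ofv(data, _unpack(x, params0, free),
                            settings.with_(inner_maxiter=60), eta_warm=None)

    # quasi-gradient descent, then a derivative-free direction-set sweep that
    # can step across curvature kinks (end-of-infusion branch switches), then
    # a second sweep if the first still moved; the fixed warm-start reference
    # is refreshed between stages
    nfev = 0
    visited = [x0]
    refresh_ref(x0)
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxfun": settings.outer_maxfev_grad, "ftol": settings.outer_ftol,
                 "gtol": 1e-6, "eps": settings.outer_eps})
    nfev += res.nfev
    visited.append(res.x)
    best = res
    if settings.outer_polish:
        for _sweep in range(settings.outer_max_sweeps):
            refresh_ref(best.x)
            res_p = optimize.minimize(
                objective, best.x, method="Powell",
                options={"maxfev": settings.outer_maxfev_sweep,
                         "ftol": 1e-8, "xtol": settings.outer_xtol})
            nfev += res_p.nfev
            visited.append(res_p.x)
            gain = best.fun - res_p.fun
            if res_p.fun < best.fun:
                best = res_p
            if gain < 0.1:
                break
    # the warm-start reference goes stale as a stage wanders, so the OFV each
    # stage *saw* can disagree with the exact value; judge every stage
    # endpoint (and the starting point) on the exact cold objective, which
    # also guarantees a warm-started nested fit never ends above its start
    converged = bool(best.success)
    best_x, best_ofv, best_eta = None, math.inf, None
    for x in visited:
        try:
            ofv_x, eta_x = final_ofv(x)
        except EstimationError:
            continue
        if ofv_x < best_ofv:
            best_x, best_ofv, best_eta = x, ofv_x, eta_x
    if best_x is None:
        return FitResult(estimates=_unpack(best.x, params0, free), ofv=float("inf"),
                         converged=False, n_evals=nfev,
                         message="objective undefined at every stage endpoint")
    estimates = _unpack(best_x, params0, free)
    return FitResult(estimates=estimates, ofv=best_ofv, converged=converged,
                     n_evals=nfev, message=str(best.message), eta_modes=best_eta)


def lrt_covariate_step(ofv_base: float, ofv_extended: float, df: int = 1) -> LRTDecision:
    """Likelihood-ratio decision for one forward covariate step.

    Significant iff the OFV drop strictly exceeds the chi-squared 5% critical
    value (3.84 for df=1).  A materially negative drop between nested models
    flags a suspected optimizer failure.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    drop = ofv_base - ofv_extended
    crit = stats.chi2.isf(0.05, df)
    p = float(stats.chi2.sf(max(drop, 0.0), df))
    warning = None
    if drop < -0.5:
        warning = ("nested extended model increased the OFV by "
                   f"{-drop:.3g}; optimizer failure suspected")
    return LRTDecision(significant=bool(drop > crit), p_value=p, drop=float(drop),
                       df=df, warning=warning)


def screen_candidates(dataset, candidates: Sequence[CovariateCandidate],
                      settings: EstimationSettings | None = None,
                      current: FitResult | None = None):
    """One round of covariate screening against the current model.

    Fits every candidate as a one-parameter extension of the current model
    (warm-started at its estimates) and returns
    ``(current_fit, [(candidate, fit, LRTDecision), ...], failures)``.

    Because a trial fit with its candidate coefficient zeroed is itself a
    current-model point, the round guards against a stale current fit: if any
    trial's shared parameters improve the current-model OFV, the current model
    is re-polished there before the drops are judged.  This keeps the two
    sides of each likelihood-ratio test comparably converged.
    """
    settings = settings or EstimationSettings()
    data = dataset if isinstance(dataset, _FitData) else _FitData(dataset, settings)
    if current is None:
        current = fit(data, settings)
    failures: list[SelectionStep] = []
    trial_fits = []
    for cand in candidates:
        shared_init = {**settings.init,
                       **{k: v for k, v in current.estimates.items()
                          if k in settings.free or k.startswith("beta_")}}
        ext = settings.with_(
            candidates=settings.candidates + (cand,),
            free=tuple(settings.free) + (cand.param,),
            init={**shared_init, cand.param: cand.init},
        )
        # coarse profile of the candidate coefficient (cheap cold
        # evaluations) picks the warm start, so a shallow local basin at
        # zero cannot hide a real effect from the full fit
        probe = settings.with_(candidates=settings.candidates + (cand,),
                               inner_maxiter=60)
        best_beta, best_probe = cand.init, math.inf
        for beta in (-0.6, -0.3, -0.15, 0.0, 0.15, 0.3, 0.45, 0.6):
            try:
                ofv_b, _ = _laplace_ofv(
                    data, {**DEFAULT_INITIALS, **shared_init, cand.param: beta},
                    probe, eta_warm=None)
            except EstimationError:
                continue
            if ofv_b < best_probe:
                best_probe, best_beta = ofv_b, beta
        ext = ext.with_(init={**shared_init, cand.param: best_beta})
        try:
            f = fit(data, ext)
        except EstimationError as exc:
            failures.append(SelectionStep(cand.name, float("nan"), float("nan"),
                                          False, note=f"fit failed: {exc}"))
            continue
        trial_fits.append((cand, f))
    improved = None
    for cand, f in trial_fits:
        shared = {k: v for k, v in f.estimates.items() if k != cand.param}
        shared[cand.param] = 0.0
        try:
            ofv_shared, _ = _laplace_ofv(
                data, {**DEFAULT_INITIALS, **shared},
                settings.with_(inner_maxiter=60), eta_warm=None)
        except EstimationError:
            continue
        if ofv_shared < current.ofv - 0.05 and (
                improved is None or ofv_shared < improved[0]):
            improved = (ofv_shared, shared)
    if improved is not None:
        repolished = fit(data, settings.with_(init={**settings.init, **improved[1]}))
        if repolished.ofv < current.ofv:
            current = repolished
    decided = [(c, f, lrt_covariate_step(current.ofv, f.ofv, df=1))
               for c, f in trial_fits]
    return current, decided, failures


def forward_selection(dataset: pd.DataFrame,
                      candidates: Sequence[CovariateCandidate],
                      settings: EstimationSettings | None = None) -> SelectionResult:
    """Forward stepwise covariate selection by likelihood-ratio testing.

    Starting from the base model defined by ``settings``, each round fits every
    remaining candidate (one extra parameter each, warm-started at the current
    estimates), adds the candidate with the largest significant OFV drop, and
    stops when none qualifies.  Candidates whose fit fails are skipped and
    recorded in the audit trail.
    """
    settings = settings or EstimationSettings()
    data = _FitData(dataset, settings)
    current = fit(data, settings)
    base_fit = current
    selected: list[CovariateCandidate] = []
    steps: list[SelectionStep] = []
    remaining = list(candidates)
    while remaining:
        current, decided, failures = screen_candidates(
            data, remaining, settings, current=current)
        steps.extend(failures)
        accepted = [(c, f, d) for c, f, d in decided if d.significant]
        for cand, f, dec in decided:
            if not dec.significant:
                steps.append(SelectionStep(cand.name, dec.drop, dec.p_value, False,
                                           note=dec.warning or ""))
        if not accepted:
            break
        cand, f, dec = max(accepted, key=lambda t: t[2].drop)
        for c2, f2, d2 in accepted:
            if c2 is not cand:
                steps.append(SelectionStep(c2.name, d2.drop, d2.p_value, False,
                                           note="significant but not the largest drop"))
        steps.append(SelectionStep(cand.name, dec.drop, dec.p_value, True))
        selected.append(cand)
        settings = settings.with_(
            candidates=settings.candidates + (cand,),
            free=tuple(settings.free) + (cand.param,),
            init={**settings.init,
                  **{k: v for k, v in f.estimates.items()}},
        )
        current = f
        remaining = [c for c in remaining if c is not cand]
    return SelectionResult(selected=tuple(c.name for c in selected),
                           steps=tuple(steps), base_fit=base_fit, final_fit=current)
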