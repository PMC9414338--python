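"""One-compartment oral dosing model with renal and body-size covariates.

This module holds the deterministic heart of the package: the structural
steady-state concentration equation for once-daily oral rivaroxaban, the
power-function covariate model on apparent clearance (CL/F, driven by
creatinine clearance) and apparent volume (V/F, driven by body weight),
construction of individual parameters from log-normal random effects,
steady-state exposure metrics (C_MAX, C_MIN, AUC_0-24), and the
Cockcroft-Gault creatinine-clearance estimate.

Units
-----
dose mg, volume L, clearance L/h, rate constants 1/h, time h.
Concentrations are computed internally in mg/L; everything reported to the
outside world is in ng/mL (1 mg/L = 1000 ng/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

#: default once-daily dosing interval (h)
TAU_DEFAULT = 24.0

#: single documented unit conversion: concentrations mg/L -> ng/mL
MGL_TO_NGML = 1000.0

# |ka - ke| below this switches to the analytic equal-rates limit to avoid
# catastrophic cancellation in (ka - ke) denominators
_RATE_TOL = 1e-8


@dataclass(frozen=True)
class PopParams:
    """Population parameters of the final covariate model.

    Defaults are the published final estimates for Thai non-valvular AF
    patients: CL/F = 4.19 * (CrCl/57.5)**0.277 L/h, V/F = 37.5 * (WT/63)**0.412 L,
    ka = 0.697 1/h, IIV 21.94 %CV on CL/F and 75.91 %CV on ka (no IIV on V/F),
    additive residual SD 0.092 (scale set by the error-model configuration).
    """

    tv_cl: float = 4.19
    tv_v: float = 37.5
    tv_ka: float = 0.697
    beta_crcl: float = 0.277
    beta_wt: float = 0.412
    crcl_ref: float = 57.5
    wt_ref: float = 63.0
    omega2_cl: float = 0.2194 ** 2
    omega2_ka: float = 0.7591 ** 2
    omega2_v: float = 0.0
    sigma_add: float = 0.092

    def __post_init__(self) -> None:
        for name in ("tv_cl", "tv_v", "tv_ka", "crcl_ref", "wt_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PopParams.{name} must be strictly positive")
        for name in ("omega2_cl", "omega2_ka", "omega2_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"PopParams.{name} must be non-negative")
        if not self.sigma_add > 0:
            raise ValueError("PopParams.sigma_add must be strictly positive")

    @property
    def eta_components(self) -> tuple:
        """Active random-effect components in order (CL, ka[, V]); a
        component exists only when its variance is nonzero."""
        comps = []
        if self.omega2_cl > 0:
            comps.append("cl")
        if self.omega2_ka > 0:
            comps.append("ka")
        if self.omega2_v > 0:
            comps.append("v")
        return tuple(comps)

    @property
    def n_eta(self) -> int:
        """Number of active random-effect components."""
        return len(self.eta_components)


#: published final model parameterization (module-level convenience instance)
FINAL_MODEL = PopParams()


@dataclass(frozen=True)
class PatientCovariates:
    """Covariates of one subject as used by the covariate model."""

    id: int
    sex: str  # 'M' or 'F'
    age: float  # years
    wt: float  # kg
    scr: float  # serum creatinine, mg/dL
    crcl: float  # creatinine clearance, mL/min
    bmi: float | None = None  # kg/m^2, optional (only sampled on request)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.wt > 0:
            raise ValueError("wt must be positive")
        if not self.scr > 0:
            raise ValueError("scr must be positive")
        if self.crcl < 15:
            raise ValueError("crcl must be >= 15 mL/min (study exclusion)")


@dataclass(frozen=True)
class IndividualParams:
    """Individual PK parameters; ke_i is derived as cl_i / v_i."""

    cl_i: float
    v_i: float
    ka_i: float
    eta: tuple = ()
    ke_i: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.cl_i > 0 and self.v_i > 0 and self.ka_i > 0):
            raise ValueError("individual rates/volumes must be positive")
        object.__setattr__(self, "ke_i", self.cl_i / self.v_i)


@dataclass(frozen=True)
class DoseRegimen:
    """Once-daily oral regimen (dose in mg, interval tau in h)."""

    dose: float
    tau: float = TAU_DEFAULT
    at_steady_state: bool = True

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summaries (ng/mL, ng*h/mL)."""

    cmax: float
    cmin: float
    auc24: float


def typical_cl(crcl, p: PopParams):
    """Typical apparent clearance CL/F (L/h) at a given CrCl (mL/min).

    CL/F = tv_cl * (CrCl / crcl_ref) ** beta_crcl.
    """
    crcl = np.asarray(crcl, dtype=float) if np.ndim(crcl) else float(crcl)
    if np.any(np.asarray(crcl) <= 0):
        raise ValueError("crcl must be strictly positive")
    return p.tv_cl * (crcl / p.crcl_ref) ** p.beta_crcl


def typical_v(wt, p: PopParams):
    """Typical apparent volume V/F (L) at a given body weight (kg).

    V/F = tv_v * (WT / wt_ref) ** beta_wt.
    """
    wt = np.asarray(wt, dtype=float) if np.ndim(wt) else float(wt)
    if np.any(np.asarray(wt) <= 0):
        raise ValueError("wt must be strictly positive")
    return p.tv_v * (wt / p.wt_ref) ** p.beta_wt


def individual_params(p: PopParams, cov: PatientCovariates, eta) -> IndividualParams:
    """Build individual parameters from covariates and log-scale random effects.

    ``eta`` has one entry per active variance component, ordered (CL, ka[, V]);
    the V component exists only when omega2_v > 0.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    comps = p.eta_components
    if eta.size != len(comps):
        raise ValueError(
            f"eta has length {eta.size}, expected {len(comps)} "
            f"(components {comps})"
        )
    e = dict(zip(comps, eta))
    cl_i = float(typical_cl(cov.crcl, p)) * math.exp(e.get("cl", 0.0))
    ka_i = p.tv_ka * math.exp(e.get("ka", 0.0))
    v_i = float(typical_v(cov.wt, p)) * math.exp(e.get("v", 0.0))
    return IndividualParams(cl_i=cl_i, v_i=v_i, ka_i=ka_i, eta=tuple(eta))


def steady_state_conc(t, dose, tau, cl, v, ka):
    """Steady-state concentration (ng/mL) for first-order absorption/elimination.

    Vectorized superposition solution

        C(t) = (D*ka) / (V*(ka-ke)) * [ exp(-ke*t)/(1-exp(-ke*tau))
                                        - exp(-ka*t)/(1-exp(-ka*tau)) ]

    with the analytic ka->ke limit used when |ka - ke| < 1e-8.  All arguments
    broadcast; ``cl``, ``v``, ``ka`` may be complex (complex-step
    differentiation in the estimation layer relies on this).
    """
    t = np.asarray(t)
    ke = cl / v
    delta = ka - ke
    small = np.abs(np.real(np.asarray(delta))) < _RATE_TOL
    safe_delta = np.where(small, 1.0, delta)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        acc_ke = np.exp(-ke * t) / (1.0 - np.exp(-ke * tau))
        acc_ka = np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
        general = dose * ka / (v * safe_delta) * (acc_ke - acc_ka)
        # equal-rates limit: continuity branch for ka ~= ke
        e_t = np.exp(-ke * t)
        d1 = 1.0 - np.exp(-ke * tau)
        limit = dose * ke / v * (
            t * e_t / d1 + tau * np.exp(-ke * tau) * e_t / d1 ** 2
        )
    out = np.where(small, limit, general) * MGL_TO_NGML
    return out


def conc_ss(t_after_dose, reg: DoseRegimen, ip: IndividualParams):
    """Steady-state concentration (ng/mL) at time(s) after dose."""
    t = np.asarray(t_after_dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_after_dose must be non-negative")
    c = steady_state_conc(t, reg.dose, reg.tau, ip.cl_i, ip.v_i, ip.ka_i)
    c = np.real(c)
    return float(c) if np.ndim(t_after_dose) == 0 else c


def t_max_ss(reg: DoseRegimen, ip: IndividualParams) -> float:
    """Time of the steady-state peak within one dosing interval (h).

    Closed form  t_max = ln[ ka(1-e^{-ke*tau}) / (ke(1-e^{-ka*tau})) ] / (ka-ke),
    with a bounded numeric search fallback for the ka ~= ke degeneracy.
    """
    ka, ke, tau = ip.ka_i, ip.ke_i, reg.tau
    if abs(ka - ke) >= _RATE_TOL:
        num = ka * (1.0 - math.exp(-ke * tau))
        den = ke * (1.0 - math.exp(-ka * tau))
        tmax = math.log(num / den) / (ka - ke)
        if 0.0 <= tmax <= tau:
            return tmax
    res = minimize_scalar(
        lambda t: -conc_ss(t, reg, ip), bounds=(0.0, tau), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def exposure_metrics(reg: DoseRegimen, ip: IndividualParams) -> ExposureMetrics:
    """Steady-state C_MAX, C_MIN (ng/mL) and AUC_0-24 (ng*h/mL).

    AUC over one interval at steady state is dose/CL (linear kinetics); no
    residual error is applied to exposure metrics.
    """
    if reg.dose == 0:
        return ExposureMetrics(cmax=0.0, cmin=0.0, auc24=0.0)
    cmax = conc_ss(t_max_ss(reg, ip), reg, ip)
    cmin = conc_ss(reg.tau, reg, ip)
    auc24 = MGL_TO_NGML * reg.dose / ip.cl_i
    return ExposureMetrics(cmax=float(cmax), cmin=float(cmin), auc24=float(auc24))


def cockcroft_gault(age, wt, scr, sex):
    """Cockcroft-Gault creatinine clearance (mL/min).

    CrCl = (140 - age) * wt / (72 * scr), multiplied by 0.85 for females.
    ``sex`` accepts 'M'/'F' (or 'male'/'female', case-insensitive).
    """
    age = float(age)
    wt = float(wt)
    scr = float(scr)
    if not (age > 0 and wt > 0 and scr > 0):
        raise ValueError("age, wt and scr must be strictly positive")
    if age >= 140:
        raise ValueError("age must be below 140 years")
    s = str(sex).upper()
    if s in ("F", "FEMALE", "0"):
        factor = 0.85
    elif s in ("M", "MALE", "1"):
        factor = 1.0
    else:
        raise ValueError(f"unrecognized sex {sex!r}")
    return factor * (140.0 - age) * wt / (72.0 * scr)
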