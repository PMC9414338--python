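"""Nonlinear mixed-effects estimation by FOCE with a frequentist ka prior.

The marginal -2 log-likelihood is approximated by first-order conditional
estimation (FOCE): for each subject the conditional mode eta_hat of the
penalized deviance

    sum_j (y_ij - f_ij(eta))^2 / sigma^2 + n_i log(2 pi sigma^2)
        + eta' Omega^{-1} eta

is found by damped Gauss-Newton, the model is linearized about eta_hat with
Jacobian G_i = df_i/deta, and the objective is

    OFV = sum_i [ log det V_i + r_i' V_i^{-1} r_i + n_i log 2 pi ]  + prior,
    V_i = G_i Omega G_i' + sigma^2 I,   r_i = y_i - f_i(eta_hat) + G_i eta_hat.

With a purely additive error model (on the configured scale) the FOCE
"interaction" term is vacuous: sigma does not depend on eta, so FOCE-I and
FOCE coincide here.

Because only steady-state peak and trough samples are available, the typical
absorption rate constant and its variability are weakly identified; a
frequentist prior anchors them:

    penalty = (tv_ka - mu_ka)^2 / se_ka^2
              + nu * ( omega2_ka_prior / omega2_ka + log omega2_ka ).

Jacobians with respect to eta use complex-step differentiation (exact to
machine precision); subjects sharing an observation count are processed as a
batch, which is what makes bootstrap and covariate-search loops affordable.
Estimation itself uses no random numbers: results are deterministic given
the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .data import EventDataset
from .model import PopParams, steady_state_conc

LOG_ADDITIVE = "log-additive"
LINEAR_ADDITIVE = "additive"

_BIG = 1e10
_CSTEP = 1e-20

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Effect:
    """One covariate effect on a structural parameter.

    Continuous covariates enter as power functions centered at ``ref``;
    the categorical sex effect enters as a multiplicative factor exp(beta)
    for males (reference level female).  One degree of freedom each.
    """

    param: str  # 'cl', 'v' or 'ka'
    cov: str  # 'crcl', 'wt', 'age', 'scr', 'bmi' or 'sex'
    ref: float = 1.0
    kind: str = "power"  # 'power' or 'factor'

    def __post_init__(self) -> None:
        if self.param not in ("cl", "v", "ka"):
            raise ValueError("effect target must be 'cl', 'v' or 'ka'")
        if self.kind == "power" and not self.ref > 0:
            raise ValueError("centering value must be positive")

    @property
    def name(self) -> str:
        return f"{self.cov}_on_{self.param}"


#: covariate structure of the final model: CrCl on CL/F, weight on V/F
FINAL_EFFECTS = (Effect("cl", "crcl", 57.5), Effect("v", "wt", 63.0))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the frequentist prior on ka and its IIV."""

    mu_ka: float = 0.61  # 1/h, midpoint of absorption rates in Asian cohorts
    se_ka: float = 0.10
    omega2_ka_prior: float = 0.76 ** 2  # matches 76 %CV
    nu: float = 10.0  # prior weight (degrees of freedom) on the variance

    def __post_init__(self) -> None:
        for name in ("mu_ka", "se_ka", "omega2_ka_prior", "nu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PriorSpec.{name} must be positive")


@dataclass
class FitConfig:
    """Estimation configuration (error scale, covariate structure, tolerances)."""

    error_model: str = LOG_ADDITIVE
    effects: tuple = FINAL_EFFECTS
    estimate_omega_v: bool = False
    tau: float = 24.0
    maxiter: int = 400
    fd_step: float = 1e-5  # outer finite-difference gradient step
    inner_maxiter: int = 60
    inner_tol: float = 1e-11
    compute_se: bool = True
    hessian_step: float = 1e-4
    # the usual pharmacometric heuristic: eigenvalue ratio above 1000
    # signals an ill-conditioned (weakly identified) fit
    cond_threshold: float = 1e3


@dataclass
class FitResult:
    """Estimates, uncertainty, OFV, empirical Bayes etas and diagnostics."""

    theta: dict
    se: dict
    rse: dict
    ofv: float
    subject_ids: list
    eta_hat: np.ndarray  # (n_subjects, n_eta), rows aligned with subject_ids
    eta_names: tuple
    eta_shrinkage: dict  # % per component (None where omega^2 = 0)
    eps_shrinkage: float
    iiv_cv: dict  # %CV = 100*sqrt(omega2)
    converged: bool
    n_iter: int
    grad_norm: float
    message: str
    ill_conditioned: bool
    hessian_cond: float | None
    config: FitConfig
    prior: PriorSpec | None
    estimates: PopParams | None = None

    def to_text(self) -> str:
        lines = ["# rivapk fit result",
                 f"ofv: {self.ofv:.6f}",
                 f"converged: {self.converged}",
                 f"n_iterations: {self.n_iter}",
                 f"gradient_norm: {self.grad_norm:.3e}",
                 f"ill_conditioned: {self.ill_conditioned}",
                 f"error_model: {self.config.error_model}",
                 "", "# parameter estimates (units: CL/F L/h, V/F L, ka 1/h,",
                 "# exponents dimensionless, omega2 log-scale variance,",
                 "# sigma on the configured error scale)"]
        for k, v in self.theta.items():
            se = self.se.get(k)
            rse = self.rse.get(k)
            extra = "" if se is None or not np.isfinite(se) else \
                f"  se={se:.5g}  rse%={rse:.3g}"
            lines.append(f"{k}: {v:.6g}{extra}")
        lines.append("")
        for k, v in self.iiv_cv.items():
            lines.append(f"iiv_cv_{k}: {v:.4g} %")
        for k, v in self.eta_shrinkage.items():
            lines.append(f"eta_shrinkage_{k}: "
                         + ("NA" if v is None else f"{v:.4g} %"))
        lines.append(f"eps_shrinkage: {self.eps_shrinkage:.4g} %")
        if self.prior is not None:
            lines.append(f"prior: mu_ka={self.prior.mu_ka} "
                         f"se_ka={self.prior.se_ka} "
                         f"omega2_ka_prior={self.prior.omega2_ka_prior} "
                         f"nu={self.prior.nu}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


# ---------------------------------------------------------------------------
# parameter vector handling

_LOG_SCALE_PREFIXES = ("tv_", "omega2_", "sigma")


def _param_names(config: FitConfig) -> list[str]:
    names = ["tv_cl", "tv_v", "tv_ka"]
    names += [e.name for e in config.effects]
    names += ["omega2_cl", "omega2_ka"]
    if config.estimate_omega_v:
        names.append("omega2_v")
    names.append("sigma")
    return names


def _is_log_scale(name: str) -> bool:
    return name.startswith(_LOG_SCALE_PREFIXES)


def _pack(theta: dict, names: list[str]) -> np.ndarray:
    return np.array([math.log(theta[n]) if _is_log_scale(n) else theta[n]
                     for n in names])


def _unpack(x: np.ndarray, names: list[str]) -> dict:
    return {n: (math.exp(v) if _is_log_scale(n) else float(v))
            for n, v in zip(names, x)}


def default_init(config: FitConfig, prior: PriorSpec | None = None) -> dict:
    """Neutral starting values: plausible typical values, covariate effects
    at zero, moderate variability."""
    th = {"tv_cl": 5.0, "tv_v": 45.0,
          "tv_ka": prior.mu_ka if prior else 0.7}
    for e in config.effects:
        th[e.name] = 0.0
    th["omega2_cl"] = 0.09
    th["omega2_ka"] = prior.omega2_ka_prior if prior else 0.3
    if config.estimate_omega_v:
        th["omega2_v"] = 0.04
    th["sigma"] = 0.15
    return th


def theta_from_popparams(p: PopParams, config: FitConfig) -> dict:
    """Map a PopParams container onto the named parameter dictionary of a
    fit configuration (covariate betas default to the matching PopParams
    exponent where the effect is the canonical one, else 0)."""
    th = {"tv_cl": p.tv_cl, "tv_v": p.tv_v, "tv_ka": p.tv_ka}
    for e in config.effects:
        if e.name == "crcl_on_cl":
            th[e.name] = p.beta_crcl
        elif e.name == "wt_on_v":
            th[e.name] = p.beta_wt
        else:
            th[e.name] = 0.0
    th["omega2_cl"] = p.omega2_cl
    th["omega2_ka"] = p.omega2_ka
    if config.estimate_omega_v:
        th["omega2_v"] = p.omega2_v if p.omega2_v > 0 else 0.04
    th["sigma"] = p.sigma_add
    return th


def popparams_from_theta(theta: dict, config: FitConfig) -> PopParams | None:
    """Inverse mapping when the covariate structure is the canonical one."""
    names = {e.name for e in config.effects}
    if not names <= {"crcl_on_cl", "wt_on_v"}:
        return None
    refs = {e.name: e.ref for e in config.effects}
    return PopParams(
        tv_cl=theta["tv_cl"], tv_v=theta["tv_v"], tv_ka=theta["tv_ka"],
        beta_crcl=theta.get("crcl_on_cl", 0.0),
        beta_wt=theta.get("wt_on_v", 0.0),
        crcl_ref=refs.get("crcl_on_cl", 57.5),
        wt_ref=refs.get("wt_on_v", 63.0),
        omega2_cl=theta["omega2_cl"], omega2_ka=theta["omega2_ka"],
        omega2_v=theta.get("omega2_v", 0.0), sigma_add=theta["sigma"],
    )


# ---------------------------------------------------------------------------
# workspace: subjects grouped by observation count for batched linear algebra

class _Group:
    __slots__ = ("ids", "y", "t", "dose", "occ", "covs", "n", "_tiles")

    def __init__(self, ids, y, t, dose, occ, covs):
        self.ids = ids
        self.y = y  # (S, n) on the error scale
        self.t = t
        self.dose = dose
        self.occ = occ
        self.covs = covs  # dict cov-name -> (S,)
        self.n = y.shape[1]
        self._tiles = {}

    def tiled(self, m: int) -> "_Group":
        """View with every subject repeated ``m`` times (stacked-variant
        evaluation); cached since tiling cost would dominate small groups."""
        if m not in self._tiles:
            self._tiles[m] = _Group(
                self.ids, np.tile(self.y, (m, 1)), np.tile(self.t, (m, 1)),
                np.tile(self.dose, (m, 1)), np.tile(self.occ, (m, 1)),
                {k: np.tile(v, m) for k, v in self.covs.items()})
        return self._tiles[m]


def _build_groups(ds: EventDataset, config: FitConfig) -> list[_Group]:
    subs = ds.to_subjects()
    if not subs:
        raise ValueError("dataset has no subjects")
    by_n: dict[int, list] = {}
    for s in subs:
        if len(s.times) < 1:
            raise ValueError(f"subject {s.id} has no observations")
        by_n.setdefault(len(s.times), []).append(s)
    groups = []
    for n, members in sorted(by_n.items()):
        y = np.stack([m.dv for m in members])
        if config.error_model == LOG_ADDITIVE:
            if np.any(y <= 0):
                raise ValueError("log-additive error requires positive DV")
            y = np.log(y)
        else:
            y = y / 1000.0  # residuals on the mg/L scale
        t = np.stack([m.times for m in members])
        dose = np.stack([m.dose for m in members])
        occ = np.stack([m.occ for m in members])
        covs = {
            "crcl": np.array([m.crcl for m in members]),
            "wt": np.array([m.wt for m in members]),
            "age": np.array([m.age for m in members]),
            "scr": np.array([m.scr for m in members]),
            "bmi": np.array([m.bmi for m in members]),
            "sex": np.array([float(m.sex_male) for m in members]),
        }
        groups.append(_Group([m.id for m in members], y, t, dose, occ, covs))
    return groups


def _eta_layout(theta: dict, config: FitConfig) -> tuple:
    layout = []
    if theta["omega2_cl"] > 0:
        layout.append("cl")
    if theta["omega2_ka"] > 0:
        layout.append("ka")
    if config.estimate_omega_v and theta.get("omega2_v", 0.0) > 0:
        layout.append("v")
    return tuple(layout)


def _effect_multiplier(e: Effect, grp: _Group, beta: float):
    cov = grp.covs[e.cov]
    if e.kind == "factor" or e.cov == "sex":
        return np.exp(beta * cov)
    if np.any(~np.isfinite(cov)) or np.any(cov <= 0):
        raise ValueError(f"covariate {e.cov!r} missing or non-positive")
    return (cov / e.ref) ** beta


def _subject_params(theta: dict, eta: np.ndarray, grp: _Group,
                    config: FitConfig, layout: tuple):
    idx = {name: k for k, name in enumerate(layout)}
    one = np.ones(len(grp.covs["crcl"]))
    cl = theta["tv_cl"] * (np.exp(eta[:, idx["cl"]]) if "cl" in idx else one)
    ka = theta["tv_ka"] * (np.exp(eta[:, idx["ka"]]) if "ka" in idx else one)
    v = theta["tv_v"] * (np.exp(eta[:, idx["v"]]) if "v" in idx else one)
    for e in config.effects:
        m = _effect_multiplier(e, grp, theta[e.name])
        if e.param == "cl":
            cl = cl * m
        elif e.param == "v":
            v = v * m
        else:
            ka = ka * m
    return cl, v, ka


def _fpred(theta: dict, eta: np.ndarray, grp: _Group, config: FitConfig,
           layout: tuple) -> np.ndarray:
    # overflow in rejected trial steps is expected: the resulting inf/nan
    # deviances are discarded by the damping logic
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        cl, v, ka = _subject_params(theta, eta, grp, config, layout)
        c_ng = steady_state_conc(grp.t, grp.dose, config.tau,
                                 cl[:, None], v[:, None], ka[:, None])
        if config.error_model == LOG_ADDITIVE:
            return np.log(c_ng)
        return c_ng / 1000.0


def _f_and_jac(theta, eta, grp, config, layout):
    S, q = eta.shape
    m = 1 + q
    ec = np.tile(eta.astype(complex), (m, 1, 1))
    for k in range(q):
        ec[1 + k, :, k] += 1j * _CSTEP
    out = _fpred(theta, ec.reshape(m * S, q), grp.tiled(m), config, layout)
    out = out.reshape(m, S, grp.n)
    return np.real(out[0]), np.moveaxis(out[1:].imag / _CSTEP, 0, -1)


def _cond_deviance(theta, eta, grp, config, layout, oinv, sig2):
    f = np.real(_fpred(theta, eta, grp, config, layout))
    r = grp.y - f
    return (r * r).sum(axis=1) / sig2 + ((eta * eta) * oinv).sum(axis=1)


def _f_jac_hess(theta, eta, grp, config, layout):
    """Prediction, Jacobian and second-derivative tensor wrt eta.

    First derivatives by complex step (exact); second derivatives by a
    central real difference of the complex-step derivative.  All variants
    are stacked into one batched model evaluation: per-call numpy overhead
    dominates at these array sizes.
    """
    S, q = eta.shape
    h2 = 1e-5
    pairs = [(k, l) for k in range(q) for l in range(k, q)]
    m = 1 + q + 2 * len(pairs)
    ec = np.tile(eta.astype(complex), (m, 1, 1))  # (m, S, q)
    for k in range(q):
        ec[1 + k, :, k] += 1j * _CSTEP
    for j, (k, l) in enumerate(pairs):
        ec[1 + q + 2 * j, :, k] += 1j * _CSTEP
        ec[1 + q + 2 * j, :, l] += h2
        ec[2 + q + 2 * j, :, k] += 1j * _CSTEP
        ec[2 + q + 2 * j, :, l] -= h2
    out = _fpred(theta, ec.reshape(m * S, q), grp.tiled(m), config, layout)
    out = out.reshape(m, S, grp.n)
    f = np.real(out[0])
    J = np.moveaxis(out[1:1 + q].imag / _CSTEP, 0, -1)
    T = np.empty(f.shape + (q, q))
    for j, (k, l) in enumerate(pairs):
        d = (out[1 + q + 2 * j].imag - out[2 + q + 2 * j].imag) \
            / (2.0 * h2 * _CSTEP)
        T[..., k, l] = d
        T[..., l, k] = d
    return f, J, T


def _modes_for_group(theta, grp, config, layout, om2, sig, eta0,
                     cold: bool = True):
    """Conditional modes for a batch of subjects.

    Newton runs from eta = 0 (the mode basin connected to the population
    center); when a warm start from the previous outer iteration is
    supplied, Newton also runs from it and the per-subject better mode
    wins.  The conditional deviance can be bimodal in eta_ka (absorption
    "flip-flop": a peak sample may be explained by fast absorption or fast
    elimination); this mode-tracking scheme deliberately follows the basin
    continuous in the outer path rather than hopping to the global
    deviance minimum, which destabilizes the outer search and, checked
    against dense-quadrature exact marginals, approximates the likelihood
    no better.
    """
    S = grp.y.shape[0]
    q = len(layout)
    oinv = 1.0 / om2
    sig2 = sig * sig
    warm_ok = eta0 is not None and eta0.shape == (S, q)
    eta = None
    if cold or not warm_ok:
        start = np.zeros((S, q))
        val = _cond_deviance(theta, start, grp, config, layout, oinv, sig2)
        eta, val = _newton_modes(theta, grp, config, layout, om2, sig,
                                 start, val)
    if warm_ok:
        val_w = _cond_deviance(theta, eta0, grp, config, layout, oinv, sig2)
        eta_w, val_w = _newton_modes(theta, grp, config, layout, om2, sig,
                                     eta0.copy(), val_w)
        if eta is None:
            return eta_w
        better = np.isfinite(val_w) & (val_w < val)
        eta[better] = eta_w[better]
        val[better] = val_w[better]
    return eta


def _newton_modes(theta, grp, config, layout, om2, sig, eta, val):
    """Damped (Levenberg-Marquardt) Newton with exact Hessians, vectorized
    across the batch; quadratically convergent near a mode."""
    S = grp.y.shape[0]
    q = len(layout)
    oinv = 1.0 / om2
    sig2 = sig * sig
    qi = np.arange(q)
    lam = np.zeros(S)
    gtol = 1e-7
    for it in range(config.inner_maxiter):
        f, J, T = _f_jac_hess(theta, eta, grp, config, layout)
        r = grp.y - f
        g = -2.0 * np.einsum("snq,sn->sq", J, r) / sig2 + 2.0 * eta * oinv
        gmax = np.abs(g).max(axis=1)
        if it > 0 and np.max(gmax) < gtol:
            break
        H = 2.0 * (np.einsum("snq,snp->sqp", J, J)
                   - np.einsum("sn,snqp->sqp", r, T)) / sig2
        H[:, qi, qi] += 2.0 * oinv
        eta_new = eta.copy()
        val_new = val.copy()
        # subjects already at their mode need no step this iteration
        pending = gmax >= gtol
        tol_acc = 1e-9 * (1.0 + np.abs(val))  # float-noise-aware acceptance
        for _ in range(25):
            Hd = H.copy()
            Hd[:, qi, qi] += lam[:, None]
            try:
                step = -np.linalg.solve(Hd, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                lam = np.minimum(np.maximum(lam * 10.0, 1e-2), 1e8)
                continue
            cand = eta + step
            vc = _cond_deviance(theta, cand, grp, config, layout, oinv, sig2)
            improve = pending & (vc <= val + tol_acc) & np.isfinite(vc)
            stalled = pending & (np.abs(step).max(axis=1) < 1e-12)
            eta_new[improve] = cand[improve]
            val_new[improve] = vc[improve]
            pending &= ~(improve | stalled)
            if not pending.any():
                break
            lam[pending] = np.minimum(np.maximum(lam[pending] * 10.0, 1e-4),
                                      1e8)
        moved = np.max(np.abs(eta_new - eta)) if S else 0.0
        eta, val = eta_new, val_new
        lam = np.where(lam > 1e-11, lam * 0.25, 0.0)
        if moved < config.inner_tol:
            break
    return eta, val


def _group_ofv(theta, grp, config, layout, om2, sig, eta):
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        f, J = _f_and_jac(theta, eta, grp, config, layout)
        r = grp.y - f + np.einsum("snq,sq->sn", J, eta)
        V = np.einsum("snq,q,smq->snm", J, om2, J)
        ni = np.arange(grp.n)
        V[:, ni, ni] += sig * sig
        if not np.all(np.isfinite(V)):
            return float("inf")
        sign, logdet = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            tr = np.trace(V, axis1=1, axis2=2)
            V[:, ni, ni] += (1e-10 * tr)[:, None]
            sign, logdet = np.linalg.slogdet(V)
        sol = np.linalg.solve(V, r[..., None])[..., 0]
        quad = (r * sol).sum(axis=1)
    return float((logdet + quad).sum() + grp.y.size * LOG2PI)


def _om2_vector(theta: dict, layout: tuple) -> np.ndarray:
    key = {"cl": "omega2_cl", "ka": "omega2_ka", "v": "omega2_v"}
    return np.array([theta[key[c]] for c in layout])


def _objective(theta, groups, config, prior, eta_cache, x=None):
    """OFV at ``theta``; ``eta_cache`` warm-starts the inner Newton.

    Warm starts are only trusted near the outer point that produced them
    (max log-scale distance 0.5): conditional-mode basins deform
    continuously along the outer path, but a cache left by a distant line
    search probe may sit in the wrong basin.
    """
    layout = _eta_layout(theta, config)
    om2 = _om2_vector(theta, layout)
    sig = theta["sigma"]
    x_ref = eta_cache.get("x")
    dist = (np.max(np.abs(x - x_ref))
            if x is not None and x_ref is not None else np.inf)
    local = dist < 0.5
    # within finite-difference-stencil distance the warm chain alone is
    # consistent; after larger moves a fresh zero start guards the basin
    cold = dist >= 1e-3
    total = 0.0
    etas = {}
    for gi, grp in enumerate(groups):
        eta0 = eta_cache.get(gi) if local else None
        if eta0 is not None and eta0.shape[1] != len(layout):
            eta0 = None
        eta = _modes_for_group(theta, grp, config, layout, om2, sig, eta0,
                               cold=cold)
        etas[gi] = eta
        total += _group_ofv(theta, grp, config, layout, om2, sig, eta)
    if np.isfinite(total):
        eta_cache.update(etas)
        if x is not None:
            eta_cache["x"] = x.copy()
    if prior is not None:
        total += prior_penalty(theta, prior)
    return total


# ---------------------------------------------------------------------------
# public operations

def prior_penalty(p, prior: PriorSpec, config: FitConfig | None = None) -> float:
    """Frequentist-prior penalty added to the OFV.

    Normal prior on the typical ka plus an inverse-chi-squared-type prior on
    its IIV variance; vanishes (up to a constant) as se_ka -> inf, nu -> 0.
    Accepts a PopParams or a theta dictionary.
    """
    if isinstance(p, PopParams):
        tv_ka, om2_ka = p.tv_ka, p.omega2_ka
    else:
        tv_ka, om2_ka = p["tv_ka"], p["omega2_ka"]
    pen = ((tv_ka - prior.mu_ka) / prior.se_ka) ** 2
    pen += prior.nu * (prior.omega2_ka_prior / om2_ka + math.log(om2_ka))
    return float(pen)


def conditional_modes(p, ds: EventDataset, config: FitConfig | None = None):
    """Empirical Bayes modes and Jacobians at fixed population parameters.

    Returns ``(subject_ids, eta_hat, jacobians)`` where ``eta_hat`` is
    (n_subjects, n_eta) and ``jacobians`` is a list of (n_i, n_eta) arrays
    G_i = df_i/deta evaluated at the mode.
    """
    config = config or FitConfig()
    theta = theta_from_popparams(p, config) if isinstance(p, PopParams) else p
    groups = _build_groups(ds, config)
    layout = _eta_layout(theta, config)
    om2 = _om2_vector(theta, layout)
    sig = theta["sigma"]
    ids, etas, jacs = [], [], []
    for grp in groups:
        eta = _modes_for_group(theta, grp, config, layout, om2, sig, None)
        _, J = _f_and_jac(theta, eta, grp, config, layout)
        ids.extend(grp.ids)
        etas.append(eta)
        jacs.extend([J[s] for s in range(len(grp.ids))])
    return ids, np.vstack(etas), jacs


def foce_objective(p, ds: EventDataset, prior: PriorSpec | None = None,
                   config: FitConfig | None = None) -> float:
    """FOCE objective function value at fixed parameters (plus prior)."""
    config = config or FitConfig()
    theta = theta_from_popparams(p, config) if isinstance(p, PopParams) else p
    groups = _build_groups(ds, config)
    return _objective(theta, groups, config, prior, {})


def fit(ds: EventDataset, init=None, prior: PriorSpec | None = PriorSpec(),
        config: FitConfig | None = None) -> FitResult:
    """Maximum (penalized) likelihood fit of the population model.

    ``init`` may be a PopParams, a theta dict or None (neutral defaults).
    Optimization runs in log space for positive parameters with a
    quasi-Newton method and finite-difference gradients; standard errors come
    from the finite-difference Hessian of the OFV (covariance = 2 H^{-1}).
    """
    config = config or FitConfig()
    if config.error_model not in (LOG_ADDITIVE, LINEAR_ADDITIVE):
        raise ValueError(f"unknown error model {config.error_model!r}")
    groups = _build_groups(ds, config)
    names = _param_names(config)
    if init is None:
        theta0 = default_init(config, prior)
    elif isinstance(init, PopParams):
        theta0 = theta_from_popparams(init, config)
    else:
        theta0 = dict(init)
    missing = [n for n in names if n not in theta0]
    if missing:
        base = default_init(config, prior)
        for n in missing:
            theta0[n] = base[n]
    x0 = _pack(theta0, names)
    eta_cache: dict = {}

    def obj(x):
        theta = _unpack(x, names)
        try:
            val = _objective(theta, groups, config, prior, eta_cache, x=x)
        except (np.linalg.LinAlgError, ValueError):
            return _BIG
        if not np.isfinite(val):
            return _BIG
        return val

    # generous box bounds keep the search away from overflow regions while
    # never binding at any plausible optimum
    bounds = [(-12.0, 12.0) if _is_log_scale(n) else (-10.0, 10.0)
              for n in names]
    res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.maxiter, "ftol": 1e-11,
                            "gtol": 1e-6, "eps": config.fd_step,
                            "maxcor": 25})
    xhat = res.x
    theta = _unpack(xhat, names)
    # re-evaluate at the solution with the final warm cache so the reported
    # OFV, empirical Bayes etas and shrinkages are mutually consistent
    ofv = float(_objective(theta, groups, config, prior, eta_cache, x=xhat))
    converged = bool(res.success) and ofv < _BIG / 2 and np.isfinite(ofv)

    # ---- uncertainty -------------------------------------------------
    se: dict = {n: float("nan") for n in names}
    rse: dict = {n: float("nan") for n in names}
    ill = False
    cond = None
    if config.compute_se:
        H = _fd_hessian(obj, xhat, config.hessian_step)
        evals = np.linalg.eigvalsh(H)
        if evals.min() <= 0:
            ill = True
            cond = float("inf")
        else:
            cond = float(evals.max() / evals.min())
            ill = cond > config.cond_threshold
            cov_x = 2.0 * np.linalg.inv(H)
            d = np.sqrt(np.clip(np.diag(cov_x), 0.0, None))
            for i, n in enumerate(names):
                se_nat = d[i] * (theta[n] if _is_log_scale(n) else 1.0)
                se[n] = float(se_nat)
                denom = abs(theta[n])
                rse[n] = float(100.0 * se_nat / denom) if denom > 0 else float("nan")

    # ---- empirical Bayes etas and shrinkage --------------------------
    layout = _eta_layout(theta, config)
    om2 = _om2_vector(theta, layout)
    sig = theta["sigma"]
    ids: list = []
    eta_rows = []
    iwres_all = []
    for gi, grp in enumerate(groups):
        eta = _modes_for_group(theta, grp, config, layout, om2, sig,
                               eta_cache.get(gi))
        f = np.real(_fpred(theta, eta, grp, config, layout))
        iwres_all.append(((grp.y - f) / sig).ravel())
        ids.extend(grp.ids)
        eta_rows.append(eta)
    eta_hat = np.vstack(eta_rows)
    iwres = np.concatenate(iwres_all)
    eta_shr: dict = {}
    comp_names = {"cl": "omega2_cl", "ka": "omega2_ka", "v": "omega2_v"}
    for comp in ("cl", "ka", "v"):
        if comp in layout:
            k = layout.index(comp)
            sd = eta_hat[:, k].std(ddof=1)
            eta_shr[comp] = float(100.0 * (1.0 - sd / math.sqrt(
                theta[comp_names[comp]])))
        elif comp == "v" and not config.estimate_omega_v:
            continue
        else:
            eta_shr[comp] = None
    eps_shr = float(100.0 * (1.0 - iwres.std(ddof=1)))
    iiv = {c: float(100.0 * math.sqrt(theta[comp_names[c]])) for c in layout}

    return FitResult(
        theta=theta, se=se, rse=rse, ofv=ofv,
        subject_ids=ids, eta_hat=eta_hat, eta_names=layout,
        eta_shrinkage=eta_shr, eps_shrinkage=eps_shr, iiv_cv=iiv,
        converged=converged, n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None
        else float("nan"),
        message=str(res.message), ill_conditioned=ill, hessian_cond=cond,
        config=config, prior=prior,
        estimates=popparams_from_theta(theta, config),
    )


def shrinkage(fr: FitResult, ds: EventDataset | None = None):
    """(eta shrinkage % per component, epsilon shrinkage %) of a fit.

    eta-shrinkage = 100 (1 - SD(eta_hat)/sqrt(omega2)); epsilon-shrinkage =
    100 (1 - SD(IWRES)).  Values are taken from the fit; components with
    omega2 = 0 are reported as None.
    """
    return fr.eta_shrinkage, fr.eps_shrinkage


def _fd_hessian(fun, x, h):
    """Central-difference Hessian (symmetrized)."""
    p = len(x)
    H = np.empty((p, p))
    f0 = fun(x)
    step = np.full(p, h)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step[i]
        fpp = fun(x + 2 * ei)
        fmm = fun(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * step[i] ** 2)
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = step[j]
            fpq = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmq = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpq - fpm - fmp + fmq) / (4 * step[i] * step[j])
    return H
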