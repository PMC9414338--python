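"""Model qualification: residual tables, visual predictive check, bootstrap.

Residuals follow the FOCE conventions: PRED is the typical prediction
(eta = 0), IPRED the individual prediction at the empirical Bayes mode,
IWRES = (y - IPRED)/sigma on the error scale, and CWRES whitens the
FOCE-linearized residual with the Cholesky factor of
V_i = G_i Omega G_i' + sigma^2 I.

The VPC bins observations by design cell (peak vs trough sampling window
crossed with crossover period) — the design has only two sampling windows,
so design-cell binning is the faithful stratification — and overlays the
observed median on the simulated 90% prediction interval.

The nonparametric bootstrap resamples subjects (never individual rows) with
replacement to the original cohort size and refits each replicate, warm
started from the original estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .data import EventDataset
from .estimate import (FitConfig, FitResult, PriorSpec, _build_groups,
                       _eta_layout, _f_and_jac, _fpred, _modes_for_group,
                       _om2_vector, _subject_params, fit)
from .model import steady_state_conc


def residual_table(fr: FitResult, ds: EventDataset) -> pd.DataFrame:
    """Per-observation PRED, IPRED, IWRES and CWRES.

    PRED/IPRED are concentrations in ng/mL; IWRES/CWRES live on the
    configured error scale.  Subjects whose V_i is not positive definite are
    flagged with NaN CWRES.  Output order follows the observation rows.
    """
    cfg = fr.config
    theta = fr.theta
    groups = _build_groups(ds, cfg)
    layout = _eta_layout(theta, cfg)
    om2 = _om2_vector(theta, layout)
    sig = theta["sigma"]
    frames = []
    for grp in groups:
        S, n = grp.y.shape
        eta = _modes_for_group(theta, grp, cfg, layout, om2, sig, None)
        f, J = _f_and_jac(theta, eta, grp, cfg, layout)
        f0 = np.real(_fpred(theta, np.zeros_like(eta), grp, cfg, layout))
        if cfg.error_model == "log-additive":
            pred, ipred = np.exp(f0), np.exp(f)
        else:
            pred, ipred = f0 * 1000.0, f * 1000.0
        iwres = (grp.y - f) / sig
        r = grp.y - f + np.einsum("snq,sq->sn", J, eta)
        cwres = np.full_like(r, np.nan)
        for s in range(S):
            V = J[s] @ (om2[:, None] * J[s].T) + sig * sig * np.eye(n)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                continue
            cwres[s] = solve_triangular(L, r[s], lower=True)
        dv = np.exp(grp.y) if cfg.error_model == "log-additive" \
            else grp.y * 1000.0
        frames.append(pd.DataFrame({
            "ID": np.repeat(grp.ids, n),
            "TIME": grp.t.ravel(),
            "DV": dv.ravel(),
            "PRED": pred.ravel(),
            "IPRED": ipred.ravel(),
            "IWRES": iwres.ravel(),
            "CWRES": cwres.ravel(),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)


@dataclass
class VpcSummary:
    """Per-design-cell simulated 90% PI and observed median."""

    table: pd.DataFrame  # columns: occ, phase, lo, hi, obs_median, n_obs
    n_simulations: int
    seed: int

    def to_text(self) -> str:
        lines = ["# visual predictive check (design-cell bins)",
                 f"n_simulations: {self.n_simulations}",
                 f"seed: {self.seed}",
                 "occ\tphase\tp5\tp95\tobs_median\tn_obs"]
        for _, r in self.table.iterrows():
            lines.append(f"{int(r.occ)}\t{r.phase}\t{r.lo:.2f}\t{r.hi:.2f}\t"
                         f"{r.obs_median:.2f}\t{int(r.n_obs)}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


def vpc(fr: FitResult, ds: EventDataset, n_sim: int = 1000,
        seed: int = 0) -> VpcSummary:
    """Simulate the exact design ``n_sim`` times from the fitted model and
    summarize the 5th/95th simulated percentiles against the observed median
    per design cell.  Deterministic under ``seed``."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    cfg = fr.config
    theta = fr.theta
    groups = _build_groups(ds, cfg)
    layout = _eta_layout(theta, cfg)
    om2 = _om2_vector(theta, layout)
    sig = theta["sigma"]
    rng = np.random.default_rng(seed)

    obs_parts, sim_parts = [], []
    for grp in groups:
        S, n = grp.y.shape
        q = len(layout)
        eta = (rng.standard_normal((n_sim, S, q)) * np.sqrt(om2)
               ).reshape(n_sim * S, q)
        tiled = _TiledGroup(grp, n_sim)
        cl, v, ka = _subject_params(theta, eta, tiled, cfg, layout)
        conc = np.real(steady_state_conc(
            np.tile(grp.t, (n_sim, 1)), np.tile(grp.dose, (n_sim, 1)),
            cfg.tau, cl[:, None], v[:, None], ka[:, None]))
        eps = rng.standard_normal(conc.shape) * sig
        if cfg.error_model == "log-additive":
            dv_sim = np.exp(np.log(conc) + eps)
        else:
            dv_sim = np.clip(conc / 1000.0 + eps, 1e-6, None) * 1000.0
        dv_obs = np.exp(grp.y) if cfg.error_model == "log-additive" \
            else grp.y * 1000.0
        occ_grp = grp.occ.astype(int)
        phase = np.where(grp.t < 12.0, "peak", "trough")
        obs_parts.append(pd.DataFrame({
            "occ": occ_grp.ravel(), "phase": phase.ravel(),
            "dv": dv_obs.ravel()}))
        sim_parts.append(pd.DataFrame({
            "occ": np.tile(occ_grp.ravel(), n_sim),
            "phase": np.tile(phase.ravel(), n_sim),
            "dv": dv_sim.ravel()}))
    obs = pd.concat(obs_parts, ignore_index=True)
    sim = pd.concat(sim_parts, ignore_index=True)
    rows = []
    for (occ, phase), g in sim.groupby(["occ", "phase"], sort=True):
        og = obs[(obs.occ == occ) & (obs.phase == phase)]
        rows.append({"occ": occ, "phase": phase,
                     "lo": float(np.percentile(g.dv, 5)),
                     "hi": float(np.percentile(g.dv, 95)),
                     "obs_median": float(np.median(og.dv)),
                     "n_obs": len(og)})
    return VpcSummary(table=pd.DataFrame(rows), n_simulations=n_sim, seed=seed)


class _TiledGroup:
    """View of a group tiled n_sim times (covariates repeat per replicate)."""

    def __init__(self, grp, reps):
        self.covs = {k: np.tile(v, reps) for k, v in grp.covs.items()}


@dataclass
class BootstrapSummary:
    """Percentile summary of bootstrap re-estimates."""

    table: pd.DataFrame  # index: parameter; median, p2.5, p97.5
    n_resamples: int
    n_failed: int
    seed: int
    unreliable: bool

    def to_text(self) -> str:
        lines = ["# nonparametric bootstrap (subject resampling)",
                 f"n_resamples: {self.n_resamples}",
                 f"n_failed: {self.n_failed}",
                 f"seed: {self.seed}",
                 f"unreliable: {self.unreliable}",
                 "parameter\tmedian\tp2.5\tp97.5"]
        for name, r in self.table.iterrows():
            lines.append(f"{name}\t{r['median']:.6g}\t{r['p2.5']:.6g}\t"
                         f"{r['p97.5']:.6g}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


def bootstrap(ds: EventDataset, init=None,
              prior: PriorSpec | None = PriorSpec(), n: int = 1000,
              seed: int = 0, config: FitConfig | None = None,
              base_fit: FitResult | None = None) -> BootstrapSummary:
    """Subject-level nonparametric bootstrap of the model parameters.

    Each replicate resamples subject ids with replacement to the original
    cohort size and refits, warm started from the original fit.  Replicate
    seeds derive from the master seed by a counter scheme.  Summaries are
    medians and 2.5/97.5 percentiles over converged replicates; the summary
    is flagged unreliable when more than 20% of replicates fail.
    """
    config = config or FitConfig()
    if base_fit is None:
        base_fit = fit(ds, init=init, prior=prior,
                       config=replace(config, compute_se=False))
    if not base_fit.converged:
        raise RuntimeError("base fit did not converge; bootstrap aborted")
    ids = ds.subject_ids
    cfg = replace(config, compute_se=False)
    results = []
    n_failed = 0
    for b in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        chosen = [ids[k] for k in rng.integers(0, len(ids), size=len(ids))]
        rep = ds.subset(chosen)
        try:
            fr = fit(rep, init=base_fit.theta, prior=prior, config=cfg)
        except Exception:
            n_failed += 1
            continue
        if not (fr.converged and np.isfinite(fr.ofv)):
            n_failed += 1
            continue
        results.append(fr.theta)
    if not results:
        raise RuntimeError("all bootstrap replicates failed")
    frame = pd.DataFrame(results)
    table = pd.DataFrame({
        "median": frame.median(),
        "p2.5": frame.quantile(0.025),
        "p97.5": frame.quantile(0.975),
    })
    return BootstrapSummary(table=table, n_resamples=n, n_failed=n_failed,
                            seed=seed, unreliable=(n_failed > 0.2 * n))


def plot_vpc(summary: VpcSummary, path) -> Path:
    """Concentration-vs-design-cell plot of the VPC bands (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = summary.table.sort_values(["occ", "phase"])
    x = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(x, tab.lo, tab.hi, alpha=0.3, label="simulated 90% PI")
    ax.plot(x, tab.obs_median, "o-", color="crimson", label="observed median")
    ax.set_xticks(x)
    ax.set_xticklabels([f"occ {int(o)}\n{p}" for o, p in
                        zip(tab.occ, tab.phase)])
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
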