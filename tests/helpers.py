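"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the
superposition oracle accumulates single-dose profiles term by term, and the
quadrature oracle integrates each subject's marginal likelihood with
adaptive Gauss-Hermite quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize

from rivapk import estimate as est
from rivapk.data import build_dataset
from rivapk.model import PopParams, steady_state_conc


def superposition_conc(t, dose, tau, cl, v, ka, n_doses=200):
    """Steady-state concentration (ng/mL) as an explicit sum of single-dose
    contributions C1(t + m*tau), m = 0..n_doses-1."""
    ke = cl / v
    total = 0.0
    for m in range(n_doses):
        tt = t + m * tau
        total += dose * ka / (v * (ka - ke)) * (
            math.exp(-ke * tt) - math.exp(-ka * tt))
    return 1000.0 * total


def agq_neg2ll(theta, ds, config, n_nodes=64):
    """Exact marginal -2 log-likelihood by adaptive Gauss-Hermite quadrature.

    Centers probabilists' Gauss-Hermite nodes at each subject's posterior
    mode, scales by the local curvature (numeric Hessian), and integrates
    the exact (non-linearized) integrand.
    """
    layout = est._eta_layout(theta, config)
    om2 = est._om2_vector(theta, layout)
    sig = theta["sigma"]
    sig2 = sig * sig
    q = len(layout)
    z, w = hermegauss(n_nodes)
    if q == 1:
        zz = z.reshape(-1, 1)
        ww = w
    else:
        Z1, Z2 = np.meshgrid(z, z, indexing="ij")
        zz = np.stack([Z1.ravel(), Z2.ravel()], axis=1)
        ww = np.outer(w, w).ravel()
    total = 0.0
    for grp in est._build_groups(ds, config):
        S, n = grp.y.shape
        for s in range(S):
            sub = est._Group(
                [grp.ids[s]], grp.y[s:s + 1], grp.t[s:s + 1],
                grp.dose[s:s + 1], grp.occ[s:s + 1],
                {k: v[s:s + 1] for k, v in grp.covs.items()})

            def nlp(e):
                e = np.asarray(e, dtype=float).reshape(1, q)
                f = np.real(est._fpred(theta, e, sub, config, layout))[0]
                r = sub.y[0] - f
                return 0.5 * ((r * r).sum() / sig2
                              + n * math.log(2 * math.pi * sig2)
                              + (e[0] ** 2 / om2).sum()
                              + q * math.log(2 * math.pi)
                              + np.log(om2).sum())

            mode = minimize(nlp, np.zeros(q), method="BFGS").x
            h = 1e-4
            H = np.zeros((q, q))
            for i in range(q):
                for j in range(q):
                    ei = np.zeros(q)
                    ei[i] = h
                    ej = np.zeros(q)
                    ej[j] = h
                    H[i, j] = (nlp(mode + ei + ej) - nlp(mode + ei - ej)
                               - nlp(mode - ei + ej) + nlp(mode - ei - ej)
                               ) / (4 * h * h)
            L = np.linalg.cholesky(np.linalg.inv(H))
            pts = mode + zz @ L.T
            vals = np.array([nlp(p) for p in pts])
            logint = -vals + 0.5 * (zz * zz).sum(axis=1)
            m = logint.max()
            integral = (ww * np.exp(logint - m)).sum() * abs(np.linalg.det(L))
            total += -2.0 * (m + np.log(integral))
    return total


def rich_design_dataset(p: PopParams, n_subjects=2, seed=0,
                        times=tuple(np.arange(1.0, 24.0, 2.0)), dose=20.0):
    """Single-occasion dataset with dense sampling (one dose, many samples
    per subject) simulated from ``p`` with log-additive residual error."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_subjects + 1):
        crcl = rng.uniform(40.0, 80.0)
        wt = rng.uniform(50.0, 80.0)
        e_cl = rng.standard_normal() * math.sqrt(p.omega2_cl)
        e_ka = rng.standard_normal() * math.sqrt(p.omega2_ka)
        cl = p.tv_cl * (crcl / p.crcl_ref) ** p.beta_crcl * math.exp(e_cl)
        v = p.tv_v * (wt / p.wt_ref) ** p.beta_wt
        ka = p.tv_ka * math.exp(e_ka)
        base = {"ID": i, "AGE": 70.0, "SEX": 1, "WT": wt, "SCR": 1.1,
                "CRCL": crcl}
        rows.append({**base, "OCC": 1, "TIME": 0.0, "DV": np.nan,
                     "AMT": dose, "SS": 1, "II": 24, "EVID": 1, "MDV": 1})
        for t in times:
            c = float(np.real(steady_state_conc(t, dose, 24.0, cl, v, ka)))
            dv = math.exp(math.log(c) + rng.standard_normal() * p.sigma_add)
            rows.append({**base, "OCC": 1, "TIME": float(t), "DV": dv,
                         "AMT": np.nan, "SS": 1, "II": 24, "EVID": 0,
                         "MDV": 0})
    return build_dataset(rows)
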