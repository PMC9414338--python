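"""FOCE estimation: conditional modes, objective, prior, fit, shrinkage."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import rivapk as rp
from rivapk import estimate as est
from rivapk.estimate import FitConfig, PriorSpec
from tests.helpers import agq_neg2ll, rich_design_dataset


class TestConditionalModes:
    def test_vanish_in_small_omega_limit(self, table2, study_ds):
        p = rp.PopParams(omega2_cl=1e-8, omega2_ka=1e-8)
        _, eta, _ = rp.conditional_modes(p, study_ds)
        assert np.max(np.abs(eta)) < 1e-3

    def test_matches_scalar_oracle_one_eta(self):
        # 1-D eta (omega2_ka = 0): mode must agree with a brute scalar search
        p = rp.PopParams(omega2_ka=0.0, omega2_cl=0.05)
        ds = rich_design_dataset(p, n_subjects=3, seed=8)
        cfg = FitConfig()
        theta = est.theta_from_popparams(p, cfg)
        layout = est._eta_layout(theta, cfg)
        assert layout == ("cl",)
        ids, eta, _ = rp.conditional_modes(p, ds)
        groups = est._build_groups(ds, cfg)
        grp = groups[0]
        for s in range(len(ids)):
            sub = est._Group([grp.ids[s]], grp.y[s:s + 1], grp.t[s:s + 1],
                             grp.dose[s:s + 1], grp.occ[s:s + 1],
                             {k: v[s:s + 1] for k, v in grp.covs.items()})

            def dev(e):
                f = np.real(est._fpred(theta, np.array([[e]]), sub, cfg,
                                       layout))[0]
                r = sub.y[0] - f
                return float((r * r).sum() / p.sigma_add ** 2
                             + e * e / p.omega2_cl)

            oracle = minimize_scalar(dev, bounds=(-2, 2), method="bounded",
                                     options={"xatol": 1e-12}).x
            assert eta[s, 0] == pytest.approx(oracle, abs=1e-6)

    def test_recovers_generating_eta_at_low_noise(self, table2):
        p = rp.PopParams(sigma_add=1e-4)
        rng = np.random.default_rng(3)
        true_eta = rng.standard_normal((3, 2)) * [0.2, 0.5]
        cohort = rp.generate_cohort(rp.CohortConfig(n_patients=3), seed=4)
        design = rp.assign_design(cohort, rp.CohortConfig(), seed=5)
        ds = rp.generate_observations(design, p, seed=6, eta=true_eta,
                                      with_residual=False)
        _, eta_hat, _ = rp.conditional_modes(p, ds)
        np.testing.assert_allclose(eta_hat, true_eta, atol=5e-3)


class TestFoceObjective:
    def test_agrees_with_quadrature_oracle(self, table2):
        cfg = FitConfig()
        theta = est.theta_from_popparams(table2, cfg)
        for seed in (5, 21, 42):
            ds = rich_design_dataset(table2, n_subjects=2, seed=seed)
            foce = rp.foce_objective(table2, ds)
            oracle = agq_neg2ll(theta, ds, cfg)
            assert foce == pytest.approx(oracle, rel=5e-3)

    def test_subject_order_invariance(self, table2, study_ds):
        import pandas as pd
        base = rp.foce_objective(table2, study_ds)
        blocks = [g for _, g in study_ds.df.groupby("ID", sort=False)]
        reordered = rp.EventDataset(
            pd.concat(blocks[::-1], ignore_index=True))
        assert rp.foce_objective(table2, reordered) == pytest.approx(
            base, rel=1e-9)

    def test_nested_optimum_dominates(self, study_ds, study_fit):
        # fixing the CrCl exponent at 0 can never beat the optimized model
        theta = dict(study_fit.theta)
        theta["crcl_on_cl"] = 0.0
        worse = rp.foce_objective(theta, study_ds, prior=study_fit.prior)
        assert worse >= study_fit.ofv - 1e-6


class TestPriorPenalty:
    def test_quadratic_in_fixed_effect(self):
        prior = PriorSpec()
        base = {"tv_ka": prior.mu_ka, "omega2_ka": prior.omega2_ka_prior}
        p0 = rp.prior_penalty(base, prior)
        p1 = rp.prior_penalty({**base, "tv_ka": prior.mu_ka + 0.1}, prior)
        p2 = rp.prior_penalty({**base, "tv_ka": prior.mu_ka + 0.2}, prior)
        assert p2 - p0 == pytest.approx(4 * (p1 - p0), rel=1e-9)

    def test_minimum_at_prior_values(self):
        prior = PriorSpec()
        at_prior = rp.prior_penalty(
            {"tv_ka": prior.mu_ka, "omega2_ka": prior.omega2_ka_prior}, prior)
        for dka in (-0.05, 0.05):
            for fom in (0.8, 1.25):
                off = rp.prior_penalty(
                    {"tv_ka": prior.mu_ka + dka,
                     "omega2_ka": prior.omega2_ka_prior * fom}, prior)
                assert off > at_prior

    def test_vague_prior_limit(self):
        vague = PriorSpec(se_ka=1e6, nu=1e-9)
        a = rp.prior_penalty({"tv_ka": 0.3, "omega2_ka": 0.5}, vague)
        b = rp.prior_penalty({"tv_ka": 0.9, "omega2_ka": 0.2}, vague)
        assert a == pytest.approx(b, abs=1e-4)


class TestFit:
    def test_self_consistency_from_truth(self, table2, study_ds, fast_cfg):
        fr = rp.fit(study_ds, init=table2, config=fast_cfg)
        assert fr.converged
        # estimates stay near the generating values on this design
        assert fr.theta["tv_cl"] == pytest.approx(table2.tv_cl, rel=0.10)
        assert fr.theta["tv_v"] == pytest.approx(table2.tv_v, rel=0.10)

    def test_estimates_independent_of_start(self, study_ds, table2, fast_cfg):
        a = rp.fit(study_ds, config=fast_cfg)
        b = rp.fit(study_ds, init=table2, config=fast_cfg)
        for k in a.theta:
            assert a.theta[k] == pytest.approx(b.theta[k], rel=5e-3, abs=1e-4)

    def test_fit_result_contract(self, study_fit):
        fr = study_fit
        assert fr.converged and not fr.ill_conditioned
        for k, se in fr.se.items():
            assert np.isfinite(se)
            assert fr.rse[k] == pytest.approx(
                100 * se / abs(fr.theta[k]), rel=1e-9)
        assert fr.estimates is not None
        assert fr.estimates.tv_cl == fr.theta["tv_cl"]
        assert fr.iiv_cv["cl"] == pytest.approx(
            100 * math.sqrt(fr.theta["omega2_cl"]), rel=1e-12)

    def test_trough_only_without_prior_is_ill_conditioned(self, table2):
        cohort = rp.generate_cohort(rp.CohortConfig(), seed=31)
        design = rp.assign_design(cohort, rp.CohortConfig(), seed=32)
        ds = rp.generate_observations(design, table2, seed=33)
        trough = rp.EventDataset(
            ds.df[(ds.df.EVID == 1) | (ds.df.TIME > 12)]
            .reset_index(drop=True))
        fr = rp.fit(trough, prior=None)
        assert fr.ill_conditioned
        fr_full = rp.fit(ds)
        assert not fr_full.ill_conditioned

    def test_serialization(self, study_fit, tmp_path):
        path = study_fit.save(tmp_path / "fit.txt")
        text = path.read_text()
        assert "tv_cl" in text and "eps_shrinkage" in text


class TestShrinkage:
    def test_total_shrinkage_when_modes_collapse(self):
        # direct formula check: all EBEs at zero means 100% shrinkage
        sd = np.zeros(10).std(ddof=1)
        assert 100 * (1 - sd / math.sqrt(0.05)) == pytest.approx(100.0)

    def test_rich_data_shrinkage_small(self, table2):
        times = tuple(np.linspace(0.5, 23.5, 24))
        ds = rich_design_dataset(table2, n_subjects=30, seed=17, times=times)
        fr = rp.fit(ds, config=FitConfig(compute_se=False))
        eta_shr, eps_shr = rp.shrinkage(fr)
        assert abs(eta_shr["cl"]) < 15
        assert abs(eps_shr) < 15

    def test_study_design_shrinkage_moderate(self, study_fit):
        eta_shr, eps_shr = rp.shrinkage(study_fit)
        assert eta_shr["cl"] < 20
        assert eta_shr["ka"] < 60
        assert eps_shr < 60
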