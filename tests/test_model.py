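"""Structural model, covariate equations, exposure metrics, Cockcroft-Gault."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rivapk as rp
from tests.helpers import superposition_conc

TYPICAL = rp.IndividualParams(cl_i=4.19, v_i=37.5, ka_i=0.697)
REG20 = rp.DoseRegimen(20.0)


class TestCovariateModel:
    @pytest.mark.parametrize("crcl, expected", [
        (57.5, 4.19),
        (115.0, 4.19 * 2 ** 0.277),
    ])
    def test_typical_cl_worked_values(self, table2, crcl, expected):
        assert rp.typical_cl(crcl, table2) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("wt, expected", [
        (63.0, 37.5),
        (126.0, 37.5 * 2 ** 0.412),
    ])
    def test_typical_v_worked_values(self, table2, wt, expected):
        assert rp.typical_v(wt, table2) == pytest.approx(expected, rel=1e-12)

    def test_zero_exponent_is_identity(self):
        p = rp.PopParams(beta_crcl=0.0, beta_wt=0.0)
        for x in (20.0, 57.5, 110.0):
            assert rp.typical_cl(x, p) == pytest.approx(p.tv_cl)
            assert rp.typical_v(x, p) == pytest.approx(p.tv_v)

    def test_monotone_in_covariates(self, table2):
        crcl = np.linspace(16, 110, 50)
        cl = rp.typical_cl(crcl, table2)
        assert np.all(np.diff(cl) > 0)
        wt = np.linspace(36, 119, 50)
        assert np.all(np.diff(rp.typical_v(wt, table2)) > 0)

    def test_nonpositive_covariate_rejected(self, table2):
        with pytest.raises(ValueError):
            rp.typical_cl(0.0, table2)
        with pytest.raises(ValueError):
            rp.typical_v(-5.0, table2)


class TestIndividualParams:
    def test_zero_eta_yields_typical_values(self, table2):
        cov = rp.PatientCovariates(1, "M", 70, 63.0, 1.1, 57.5)
        ip = rp.individual_params(table2, cov, [0.0, 0.0])
        assert (ip.cl_i, ip.v_i, ip.ka_i) == pytest.approx((4.19, 37.5, 0.697))
        assert ip.ke_i == pytest.approx(ip.cl_i / ip.v_i, rel=1e-15)

    def test_exponential_link(self, table2):
        cov = rp.PatientCovariates(1, "F", 70, 63.0, 1.1, 57.5)
        ip0 = rp.individual_params(table2, cov, [0.0, 0.0])
        ip = rp.individual_params(table2, cov, [math.log(2.0), 0.0])
        assert ip.cl_i == pytest.approx(2 * ip0.cl_i)

    def test_eta_length_mismatch(self, table2):
        cov = rp.PatientCovariates(1, "M", 70, 63.0, 1.1, 57.5)
        with pytest.raises(ValueError, match="eta has length"):
            rp.individual_params(table2, cov, [0.0])


class TestSteadyStateConcentration:
    def test_zero_dose_gives_zero(self):
        reg = rp.DoseRegimen(0.0)
        for t in (0.0, 3.0, 24.0):
            assert rp.conc_ss(t, reg, TYPICAL) == pytest.approx(0.0)

    def test_trough_worked_value(self):
        # typical 20 mg q24h trough ~46.6-46.7 ng/mL
        assert rp.conc_ss(24.0, REG20, TYPICAL) == pytest.approx(46.67, abs=0.1)

    def test_peak_worked_value(self):
        tmax = rp.t_max_ss(REG20, TYPICAL)
        assert tmax == pytest.approx(3.007, abs=0.01)
        assert rp.conc_ss(tmax, REG20, TYPICAL) == pytest.approx(409.2, abs=0.5)

    @pytest.mark.parametrize("t", [0.5, 3.0, 12.0, 23.9])
    def test_matches_superposition_oracle(self, t):
        oracle = superposition_conc(t, 20.0, 24.0, TYPICAL.cl_i,
                                    TYPICAL.v_i, TYPICAL.ka_i, n_doses=200)
        ours = rp.conc_ss(t, REG20, TYPICAL)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_periodicity_at_steady_state(self):
        assert rp.conc_ss(0.0, REG20, TYPICAL) == pytest.approx(
            rp.conc_ss(24.0, REG20, TYPICAL), rel=1e-10)

    def test_equal_rates_limit_continuous(self):
        # ka == ke branch agrees with nearly-equal rates and the oracle
        ke = TYPICAL.ke_i
        ip_eq = rp.IndividualParams(cl_i=ke * 37.5, v_i=37.5, ka_i=ke)
        ip_near = rp.IndividualParams(cl_i=ke * 37.5, v_i=37.5,
                                      ka_i=ke * (1 + 1e-6))
        for t in (1.0, 6.0, 23.0):
            c_eq = rp.conc_ss(t, REG20, ip_eq)
            c_near = rp.conc_ss(t, REG20, ip_near)
            assert c_eq == pytest.approx(c_near, rel=1e-4)
            oracle = superposition_conc(t, 20.0, 24.0, ip_near.cl_i,
                                        ip_near.v_i, ip_near.ka_i)
            assert c_eq == pytest.approx(oracle, rel=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rp.conc_ss(-1.0, REG20, TYPICAL)


class TestExposureMetrics:
    def test_auc_worked_value(self):
        em = rp.exposure_metrics(REG20, TYPICAL)
        assert em.auc24 == pytest.approx(1000 * 20 / 4.19, rel=1e-12)

    def test_auc_matches_trapezoid_integration(self):
        em = rp.exposure_metrics(REG20, TYPICAL)
        t = np.linspace(0.0, 24.0, 2001)
        num = np.trapezoid(rp.conc_ss(t, REG20, TYPICAL), t)
        assert em.auc24 == pytest.approx(num, rel=1e-3)

    def test_linearity_in_dose(self):
        em1 = rp.exposure_metrics(rp.DoseRegimen(10.0), TYPICAL)
        em2 = rp.exposure_metrics(rp.DoseRegimen(20.0), TYPICAL)
        assert em2.cmax == pytest.approx(2 * em1.cmax, rel=1e-9)
        assert em2.cmin == pytest.approx(2 * em1.cmin, rel=1e-9)
        assert em2.auc24 == pytest.approx(2 * em1.auc24, rel=1e-12)

    def test_cmax_exceeds_cmin(self):
        em = rp.exposure_metrics(REG20, TYPICAL)
        assert em.cmax > em.cmin > 0

    def test_zero_dose(self):
        em = rp.exposure_metrics(rp.DoseRegimen(0.0), TYPICAL)
        assert (em.cmax, em.cmin, em.auc24) == (0.0, 0.0, 0.0)


class TestCockcroftGault:
    def test_worked_values(self):
        male = rp.cockcroft_gault(70, 64, 1.1, "M")
        assert male == pytest.approx(56.57, abs=0.01)
        female = rp.cockcroft_gault(70, 64, 1.1, "F")
        assert female == pytest.approx(0.85 * male, rel=1e-12)

    @given(age=st.floats(20, 110), wt=st.floats(35, 150),
           scr=st.floats(0.4, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_structural_properties(self, age, wt, scr):
        base = rp.cockcroft_gault(age, wt, scr, "M")
        assert rp.cockcroft_gault(age, 2 * wt, scr, "M") == pytest.approx(
            2 * base, rel=1e-9)
        assert rp.cockcroft_gault(age, wt, 2 * scr, "M") == pytest.approx(
            base / 2, rel=1e-9)
        # linear in (140 - age)
        mid = (140.0 + age) / 2.0
        assert rp.cockcroft_gault(mid, wt, scr, "M") == pytest.approx(
            base / 2, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rp.cockcroft_gault(140, 64, 1.1, "M")
        with pytest.raises(ValueError):
            rp.cockcroft_gault(70, -1, 1.1, "F")


class TestPopParamsValidation:
    @pytest.mark.parametrize("kw", [
        {"tv_cl": 0.0}, {"tv_v": -1.0}, {"sigma_add": 0.0},
        {"omega2_cl": -0.1}, {"crcl_ref": 0.0},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            rp.PopParams(**kw)

    def test_eta_components_follow_nonzero_variances(self):
        assert rp.PopParams().eta_components == ("cl", "ka")
        assert rp.PopParams(omega2_ka=0.0).eta_components == ("cl",)
        assert rp.PopParams(omega2_v=0.1).eta_components == ("cl", "ka", "v")
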