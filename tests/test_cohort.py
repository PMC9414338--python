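"""Synthetic cohort, dose assignment and observation generation."""

import numpy as np
import pytest

import rivapk as rp

CFG = rp.CohortConfig()


class TestGenerateCohort:
    def test_size_and_exclusion_bound(self):
        cohort = rp.generate_cohort(CFG, seed=1)
        assert len(cohort) == 60
        assert all(c.crcl >= 15 for c in cohort)

    def test_determinism(self):
        a = rp.generate_cohort(CFG, seed=5)
        b = rp.generate_cohort(CFG, seed=5)
        assert a == b

    def test_truncation_bounds_respected(self):
        cohort = rp.generate_cohort(rp.CohortConfig(n_patients=500), seed=2)
        for c in cohort:
            assert CFG.age_bounds[0] <= c.age <= CFG.age_bounds[1]
            assert CFG.wt_bounds[0] <= c.wt <= CFG.wt_bounds[1]
            assert CFG.scr_bounds[0] <= c.scr <= CFG.scr_bounds[1]
            assert CFG.crcl_bounds[0] <= c.crcl <= CFG.crcl_bounds[1]

    def test_large_sample_moments_match_truncated_normal(self):
        from scipy import stats
        cohort = rp.generate_cohort(rp.CohortConfig(n_patients=10000), seed=3)
        crcl = np.array([c.crcl for c in cohort])
        a = (CFG.crcl_bounds[0] - CFG.crcl_mean) / CFG.crcl_sd
        b = (CFG.crcl_bounds[1] - CFG.crcl_mean) / CFG.crcl_sd
        expected = stats.truncnorm.mean(a, b, loc=CFG.crcl_mean,
                                        scale=CFG.crcl_sd)
        assert crcl.mean() == pytest.approx(expected, abs=1.0)
        male_frac = np.mean([c.sex == "M" for c in cohort])
        assert male_frac == pytest.approx(0.633, abs=0.02)

    def test_bmi_only_on_request(self):
        assert rp.generate_cohort(CFG, seed=1)[0].bmi is None
        with_bmi = rp.generate_cohort(
            rp.CohortConfig(sample_bmi=True), seed=1)
        assert all(15 < c.bmi < 45 for c in with_bmi)


class TestAssignDesign:
    def test_dose_rule_at_cutoff_boundary(self):
        mk = lambda i, crcl: rp.PatientCovariates(i, "M", 70, 64, 1.1, crcl)
        design = rp.assign_design([mk(1, 50.0), mk(2, 49.9)], CFG, seed=1)
        assert design.patients[0].doses == (20.0, 15.0)
        assert design.patients[1].doses == (15.0, 10.0)

    def test_sampling_windows(self):
        cohort = rp.generate_cohort(rp.CohortConfig(n_patients=200), seed=4)
        design = rp.assign_design(cohort, CFG, seed=5)
        for pat in design.patients:
            assert all(2.0 <= t <= 4.0 for t in pat.peak_times)
            assert all(22.0 <= t <= 24.0 for t in pat.trough_times)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            rp.assign_design([], CFG)


class TestGenerateObservations:
    def test_row_counts_for_study_design(self, table2):
        cohort = rp.generate_cohort(CFG, seed=1)
        design = rp.assign_design(cohort, CFG, seed=2)
        ds = rp.generate_observations(design, table2, seed=3)
        assert ds.n_observations == 240
        assert len(ds.doses) == 120
        counts = ds.observations.groupby("ID").size()
        assert (counts == 4).all()

    def test_noise_free_equals_typical_prediction(self, table2):
        cov = rp.PatientCovariates(1, "M", 70, 63.0, 1.1, 57.5)
        design = rp.assign_design([cov], CFG, seed=6)
        ds = rp.generate_observations(design, table2, seed=7,
                                      with_residual=False,
                                      eta=np.zeros(2))
        ip = rp.individual_params(table2, cov, [0.0, 0.0])
        for _, row in ds.observations.iterrows():
            reg = rp.DoseRegimen(
                float(ds.doses[(ds.doses.ID == row.ID)
                               & (ds.doses.OCC == row.OCC)].AMT.iloc[0]))
            assert row.DV == pytest.approx(
                rp.conc_ss(row.TIME, reg, ip), rel=1e-9)

    def test_determinism_bytewise(self, table2, tmp_path):
        cohort = rp.generate_cohort(CFG, seed=1)
        design = rp.assign_design(cohort, CFG, seed=2)
        p1 = rp.generate_observations(design, table2, seed=9).write(
            tmp_path / "a.csv")
        p2 = rp.generate_observations(design, table2, seed=9).write(
            tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_peaks_exceed_troughs_noise_free(self, table2):
        cohort = rp.generate_cohort(rp.CohortConfig(n_patients=300), seed=11)
        design = rp.assign_design(cohort, CFG, seed=12)
        ds = rp.generate_observations(design, table2, seed=13,
                                      with_residual=False)
        obs = ds.observations
        peaks = obs[obs.TIME < 12].groupby(["ID", "OCC"]).DV.min()
        troughs = obs[obs.TIME > 12].groupby(["ID", "OCC"]).DV.max()
        frac = (peaks > troughs).mean()
        assert frac > 0.99

    def test_simulate_study_is_deterministic(self, table2):
        a = rp.simulate_study(CFG, table2, seed=42)
        b = rp.simulate_study(CFG, table2, seed=42)
        assert a.df.equals(b.df)

    def test_log_error_variance_structure(self, table2):
        # var of log peak DV across a large cohort ~ omega2_cl contribution
        # + time-in-window variation + residual variance (loose MC check)
        cfg = rp.CohortConfig(n_patients=2000)
        ds = rp.simulate_study(cfg, table2, seed=21)
        obs = ds.observations
        troughs = np.log(obs[obs.TIME > 12].DV.to_numpy())
        v = np.var(troughs)
        # trough log-DV variance is dominated by eta_cl (amplified by
        # e^{-ke t} sensitivity), residual noise and the dose split
        assert v > table2.omega2_cl + table2.sigma_add ** 2
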