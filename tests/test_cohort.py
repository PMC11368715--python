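"""Synthetic cohort generator: covariate marginals, regimens, troughs."""

import numpy as np
import pytest

import voripk as vp
from voripk.cohort import (CohortConfig, DistSpec, assign_regimen,
                           generate_cohort, sample_covariates,
                           _sample_covariate_batch)
from voripk.pk import PKParameters, superpose
from voripk.records import DoseEvent, ROUTE_IV


@pytest.fixture(scope="module")
def big_covariates():
    cfg = CohortConfig()
    rng = np.random.default_rng(2)
    return _sample_covariate_batch(cfg, rng, 10_000)


class TestCovariateSampling:
    def test_phenotype_frequencies(self, big_covariates):
        phen = np.array([c.phenotype for c in big_covariates])
        for label, target in (("NM", 0.395), ("IM", 0.431), ("PM", 0.174)):
            assert np.mean(phen == label) == pytest.approx(target, abs=0.02)

    def test_age_mean_matches_cohort_summary(self, big_covariates):
        ages = np.array([c.AGE for c in big_covariates])
        assert ages.mean() == pytest.approx(68.87, abs=1.0)
        assert ages.min() >= 16.0 and ages.max() <= 97.0

    def test_crp_moments_and_range(self, big_covariates):
        crp = np.array([c.CRP for c in big_covariates])
        assert crp.mean() == pytest.approx(77.10, abs=2.5)
        assert crp.std() == pytest.approx(68.74, rel=0.08)
        assert crp.min() >= 0.9 and crp.max() <= 306.6

    def test_sex_and_comedication_rates(self, big_covariates):
        male = np.mean([c.SEX == "male" for c in big_covariates])
        ppi = np.mean([c.ppi_flag for c in big_covariates])
        steroid = np.mean([c.steroid_flag for c in big_covariates])
        assert male == pytest.approx(119 / 167, abs=0.02)
        assert ppi == pytest.approx(0.701, abs=0.02)
        assert steroid == pytest.approx(0.257, abs=0.02)

    def test_zero_sd_collapses_to_mean(self):
        dists = dict(CohortConfig().covariate_dists)
        dists["WT"] = DistSpec("truncnorm", 65.0, 0.0, 37.0, 100.0)
        cfg = CohortConfig(covariate_dists=dists)
        covs = _sample_covariate_batch(cfg, np.random.default_rng(0), 50)
        assert {c.WT for c in covs} == {65.0}

    def test_single_draw_api(self):
        cov = sample_covariates(CohortConfig(), np.random.default_rng(3))
        assert cov.AGE > 0 and cov.phenotype in ("NM", "IM", "PM")

    def test_copula_induces_correlation(self):
        r = np.array([[1.0, 0.8], [0.8, 1.0]])
        cfg = CohortConfig(copula=(("AST", "ALT"), r))
        covs = _sample_covariate_batch(cfg, np.random.default_rng(4), 4000)
        ast = np.array([c.AST for c in covs])
        alt = np.array([c.ALT for c in covs])
        from scipy.stats import spearmanr
        assert spearmanr(ast, alt).statistic > 0.6


class TestRegimens:
    def test_mix_fractions(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        covs = _sample_covariate_batch(cfg, rng, 10_000)
        arms = np.zeros(3)
        for cov in covs:
            doses = assign_regimen(cov, cfg, rng)
            if len({d.amount for d in doses}) > 1:
                arms[0 if doses[0].route == ROUTE_IV else 1] += 1
            else:
                arms[2] += 1
        frac = arms / arms.sum()
        assert frac[0] == pytest.approx(57 / 167, abs=0.02)
        assert frac[1] == pytest.approx(4 / 167, abs=0.02)
        assert frac[2] == pytest.approx(106 / 167, abs=0.02)

    def test_flat_arm_is_200_bid_without_loading(self):
        cfg = CohortConfig(regimen_mix=(0.0, 0.0, 1.0))
        rng = np.random.default_rng(6)
        cov = sample_covariates(cfg, rng)
        doses = assign_regimen(cov, cfg, rng)
        assert len(doses) == 1
        assert doses[0].amount == 200.0 and doses[0].interval == 12.0

    def test_infusion_rate_cap_respected(self, study_cohort):
        """IV infusion rate never exceeds 3 mg/kg/h."""
        for s in study_cohort:
            for d in s.doses:
                if d.route == ROUTE_IV:
                    rate = d.amount / d.infusion_duration
                    assert rate <= 3.0 * s.covariates.WT * (1 + 1e-12)

    def test_light_subject_gets_stretched_infusion(self):
        cfg = CohortConfig(regimen_mix=(1.0, 0.0, 0.0))
        cov = vp.CovariateSet(AGE=70, WT=40.0, SEX="male", ALB=35, CRP=50,
                              phenotype="NM")
        doses = assign_regimen(cov, cfg, np.random.default_rng(0))
        load = doses[0]
        # 400 mg at 40 kg: the 3 mg/kg/h cap forces > 3.3 h
        assert load.amount == 400.0
        assert load.infusion_duration >= 400.0 / (3.0 * 40.0)


class TestObservationSimulation:
    def test_no_noise_limit_equals_deterministic_trough(self):
        quiet = vp.ThetaOmegaSigma(omega_cl=0.0, omega_v=0.0,
                                   sigma_prop=0.0, sigma_add=0.0)
        cfg = CohortConfig(n_subjects=6, regimen_mix=(0.0, 0.0, 1.0),
                           second_trough_prob=0.0)
        subs = generate_cohort(cfg, seed=8, truth=quiet)
        for s in subs:
            p = PKParameters(CL=vp.typical_cl(s.covariates, quiet),
                             V=vp.typical_v(s.covariates, quiet),
                             ka=quiet.ka, F=quiet.f)
            expected = superpose(s.doses, [120.0], p)
            assert s.observations[0].time == 120.0
            assert s.observations[0].concentration == \
                pytest.approx(float(expected[0]), rel=1e-12)

    def test_trough_day_depends_on_loading(self):
        subs = generate_cohort(CohortConfig(n_subjects=300), seed=9)
        for s in subs:
            loaded = len({d.amount for d in s.doses}) > 1
            assert s.observations[0].time == (48.0 if loaded else 120.0)

    def test_trough_count_matches_study_ratio(self):
        subs = generate_cohort(CohortConfig(n_subjects=2000), seed=10)
        per_subject = np.array([len(s.observations) for s in subs])
        assert set(per_subject) <= {1, 2}
        assert per_subject.mean() == pytest.approx(232 / 167, abs=0.04)

    def test_negative_concentrations_truncated_and_flagged(self):
        noisy = vp.ThetaOmegaSigma(sigma_add=10.0)
        cfg = CohortConfig(n_subjects=100)
        subs = generate_cohort(cfg, seed=12, truth=noisy)
        concs = np.array([o.concentration for s in subs
                          for o in s.observations])
        flags = np.array([o.bql_flag for s in subs for o in s.observations])
        assert concs.min() >= cfg.lloq / 2.0
        assert np.any(concs == cfg.lloq / 2.0)
        assert all(flags[concs < cfg.lloq])

    def test_generation_is_bit_reproducible(self):
        a = generate_cohort(CohortConfig(n_subjects=25), seed=13)
        b = generate_cohort(CohortConfig(n_subjects=25), seed=13)
        assert a == b

    def test_steady_state_trough_insensitive_to_loading_arm(self):
        """With equal maintenance dosing, the trough long after the start
        is the same with or without a loading day (accumulation)."""
        p = PKParameters(CL=3.83, V=134.0, ka=1.1, F=0.965)
        flat = [DoseEvent(0.0, 200.0, ROUTE_IV, 2.0, interval=12.0,
                          n_doses=50)]
        loaded = [DoseEvent(0.0, 400.0, ROUTE_IV, 2.0, interval=12.0,
                            n_doses=2),
                  DoseEvent(24.0, 200.0, ROUTE_IV, 2.0, interval=12.0,
                            n_doses=48)]
        t = [600.0]
        np.testing.assert_allclose(superpose(flat, t, p),
                                   superpose(loaded, t, p), rtol=1e-4)

    def test_median_trough_in_plausible_range(self, study_cohort):
        """Under the final-model truth the simulated troughs sit in the
        low single-digit ug/mL range, like the studied cohort's."""
        concs = [o.concentration for s in study_cohort
                 for o in s.observations]
        assert 2.0 < np.median(concs) < 8.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(phenotype_freqs=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            DistSpec("truncnorm", 5.0, 1.0, 10.0, 1.0)
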