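"""FOCE-I engine: conditional modes, objective function, fitting,
shrinkage, and the quadrature oracle."""

import numpy as np
import pytest

import voripk as vp
from voripk.design import CohortDesign
from voripk.foce import (ParamCoder, eta_modes, ofv, ofv_quadrature,
                         shrinkage)
from voripk.records import (CovariateSet, DoseEvent, Observation,
                            SubjectRecord)

COV = dict(AGE=70.0, WT=65.0, SEX="male", ALB=34.8, CRP=59.0,
           phenotype="NM")


def rich_subject(sid="R1", eta=(0.0, 0.0), theta=None, noise=0.0, seed=0):
    """One subject with informative sampling (absorption + elimination
    phases) whose data are generated exactly from the model."""
    theta = theta or vp.ThetaOmegaSigma()
    cov = CovariateSet(**COV)
    doses = (DoseEvent(0.0, 200.0, "intravenous", 2.0),)
    p = vp.PKParameters(
        CL=vp.typical_cl(cov, theta) * np.exp(eta[0]),
        V=vp.typical_v(cov, theta) * np.exp(eta[1]), ka=theta.ka, F=theta.f)
    times = [1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0]
    conc = vp.superpose(doses, times, p)
    rng = np.random.default_rng(seed)
    y = conc * np.exp(rng.normal(0, noise, len(times)))
    return SubjectRecord(id=sid, covariates=cov, doses=doses,
                         observations=tuple(
                             Observation(t, max(float(c), 1e-6))
                             for t, c in zip(times, y)))


class TestEtaModes:
    def test_matches_dense_grid_search(self, final_spec):
        """The vectorized Newton solver lands on the same mode as a brute
        two-stage grid search over the (eta_CL, eta_V) plane."""
        theta = vp.ThetaOmegaSigma(omega_cl=0.4, omega_v=0.4,
                                   sigma_prop=0.15, sigma_add=0.3)
        subject = rich_subject(eta=(0.35, -0.25), noise=0.1, seed=4)
        design = CohortDesign.from_subjects([subject])
        eta_hat, bad = eta_modes(design, theta, final_spec)
        assert not bad.any()

        # brute force: evaluate the inner objective on replicated copies
        from voripk.foce import _inner_value
        omega_inv = np.linalg.inv(theta.omega_matrix())
        center, width, step = np.zeros(2), 1.0, 0.02
        for _ in range(3):  # coarse-to-fine refinement
            g1 = np.arange(center[0] - width, center[0] + width, step)
            g2 = np.arange(center[1] - width, center[1] + width, step)
            ee = np.stack(np.meshgrid(g1, g2, indexing="ij"),
                          axis=-1).reshape(-1, 2)
            rep = CohortDesign.from_subjects(
                [subject] * len(ee))
            tv = rep.typical_params(theta, final_spec)
            vals = _inner_value(rep, theta, final_spec, ee, omega_inv,
                                (tv[0], tv[1]))
            center = ee[np.argmin(vals)]
            width, step = 2.5 * step, step / 10.0
        assert np.allclose(eta_hat[0], center, atol=1e-3)

    def test_infinite_shrinkage_limit(self, final_spec):
        theta = vp.ThetaOmegaSigma(omega_cl=1e-6, omega_v=1e-6)
        design = CohortDesign.from_subjects([rich_subject(eta=(0.5, 0.3))])
        eta_hat, _ = eta_modes(design, theta, final_spec)
        assert np.abs(eta_hat).max() < 1e-4

    def test_small_noise_recovery(self, final_spec):
        theta = vp.ThetaOmegaSigma(omega_cl=1.0, omega_v=1.0,
                                   sigma_prop=0.001, sigma_add=0.001)
        design = CohortDesign.from_subjects(
            [rich_subject(eta=(0.3, -0.2), theta=theta)])
        eta_hat, _ = eta_modes(design, theta, final_spec)
        assert np.allclose(eta_hat[0], [0.3, -0.2], atol=0.02)


class TestOfv:
    def test_degenerate_single_observation_closed_form(self, final_spec):
        """With Omega -> 0 the marginal collapses to one normal density."""
        theta = vp.ThetaOmegaSigma(omega_cl=1e-8, omega_v=1e-8)
        s = SubjectRecord(
            id="S1", covariates=CovariateSet(**COV),
            doses=(DoseEvent(0.0, 200.0, "intravenous", 2.0),),
            observations=(Observation(12.0, 3.0),))
        design = CohortDesign.from_subjects([s])
        got = ofv(design, theta, final_spec)
        f = design.predict(*design.typical_params(theta, final_spec),
                           theta.ka, theta.f)[0]
        v = f ** 2 * theta.sigma_prop ** 2 + theta.sigma_add ** 2
        expected = np.log(v) + (3.0 - f) ** 2 / v
        assert got == pytest.approx(expected, abs=1e-4)

    def test_extra_observation_increases_ofv(self, final_spec, truth):
        s = rich_subject(noise=0.2, seed=5)
        extra = SubjectRecord(
            id=s.id, covariates=s.covariates, doses=s.doses,
            observations=s.observations + (Observation(60.0, 5.0),))
        d1 = CohortDesign.from_subjects([s])
        d2 = CohortDesign.from_subjects([extra])
        assert ofv(d2, truth, final_spec) > ofv(d1, truth, final_spec)

    def test_additive_over_subjects(self, final_spec, truth,
                                    small_cohort):
        subs = vp.apply_m1(small_cohort)[:6]
        total = ofv(CohortDesign.from_subjects(subs), truth, final_spec)
        parts = sum(ofv(CohortDesign.from_subjects([s]), truth, final_spec)
                    for s in subs)
        assert total == pytest.approx(parts, abs=1e-8)

    def test_delta_ofv_invariant_to_constant_convention(
            self, final_spec, truth, small_cohort):
        """Differences between nested models do not depend on whether the
        n log(2 pi) constant is carried."""
        design = CohortDesign.from_subjects(vp.apply_m1(small_cohort))
        other = vp.ThetaOmegaSigma(cl=3.0)
        d_drop = ofv(design, truth, final_spec) \
            - ofv(design, other, final_spec)
        d_full = ofv(design, truth, final_spec, full_constant=True) \
            - ofv(design, other, final_spec, full_constant=True)
        assert d_drop == pytest.approx(d_full, abs=1e-9)

    @pytest.mark.parametrize("n_subjects", [1, 3, 5])
    def test_agrees_with_gauss_hermite_oracle(self, final_spec, truth,
                                              n_subjects):
        """FOCE-I approximation within 2 units of a 31-node adaptive
        Gauss-Hermite evaluation of -2 log L on small cohorts."""
        subs = vp.apply_m1(
            vp.generate_cohort(vp.CohortConfig(n_subjects=n_subjects),
                               seed=40 + n_subjects))
        design = CohortDesign.from_subjects(subs)
        focei = ofv(design, truth, final_spec, full_constant=True)
        quad = ofv_quadrature(design, truth, final_spec, n_nodes=31)
        assert abs(focei - quad) <= 2.0


class TestFit:
    def test_refit_from_truth_does_not_worsen_ofv(self, final_spec, truth,
                                                  small_cohort):
        design = CohortDesign.from_subjects(vp.apply_m1(small_cohort))
        start = ofv(design, truth, final_spec)
        res = vp.fit(design, final_spec, truth, compute_se=False,
                     polish=False, maxiter=60)
        assert res.ofv <= start + 1e-6

    def test_standard_errors_reported(self, base_spec):
        subs = vp.generate_cohort(
            vp.CohortConfig(n_subjects=60), seed=14,
            truth=vp.base_model_params(), spec=base_spec)
        res = vp.fit(subs, base_spec, vp.base_model_params(),
                     compute_se=True, polish=False)
        rse = res.relative_standard_errors
        assert rse is not None
        for name in ("cl", "v", "omega_cl", "sigma_add"):
            assert np.isfinite(rse[name]) and rse[name] > 0
        assert "ka" not in rse  # fixed parameter is not estimated
        assert "OFV" in res.summary()

    def test_f_fixed_without_oral_data(self, base_spec):
        cfg = vp.CohortConfig(n_subjects=20, regimen_mix=(0.0, 0.0, 1.0),
                              oral_fraction_flat=0.0)
        subs = vp.generate_cohort(cfg, seed=15,
                                  truth=vp.base_model_params(),
                                  spec=base_spec)
        design = CohortDesign.from_subjects(vp.apply_m1(subs))
        assert not design.has_oral_obs
        coder = ParamCoder(base_spec, estimate_f=design.has_oral_obs)
        assert "f" not in coder.names

    def test_param_coder_round_trip(self, final_spec, truth):
        coder = ParamCoder(final_spec)
        x = coder.pack(truth)
        back = coder.unpack(x, truth)
        for name in coder.names:
            assert back.coef(name) == pytest.approx(truth.coef(name),
                                                    rel=1e-12)


class TestShrinkage:
    def test_rich_low_noise_data_has_low_shrinkage(self, final_spec):
        theta = vp.ThetaOmegaSigma(omega_cl=0.4, omega_v=0.4,
                                   sigma_prop=0.02, sigma_add=0.02)
        rng = np.random.default_rng(16)
        subs = [rich_subject(sid=f"R{i}", theta=theta,
                             eta=tuple(rng.normal(0, 0.4, 2)),
                             noise=0.02, seed=100 + i) for i in range(40)]
        shr_cl, shr_v, _ = shrinkage(
            CohortDesign.from_subjects(subs), theta, final_spec)
        assert shr_cl < 15.0 and shr_v < 25.0

    def test_prior_dominated_limit_shrinks_to_100(self, final_spec):
        theta = vp.ThetaOmegaSigma(omega_cl=5.0, omega_v=5.0)
        subs = [SubjectRecord(
            id=f"P{i}", covariates=CovariateSet(**COV),
            doses=(DoseEvent(0.0, 200.0, "intravenous", 2.0),),
            observations=(Observation(12.0, 3.0 + 0.1 * i),))
            for i in range(10)]
        shr_cl, shr_v, _ = shrinkage(
            CohortDesign.from_subjects(subs), theta, final_spec)
        assert shr_v > 90.0

    def test_trough_only_design_shrinks_v_more_than_cl(
            self, study_design, truth, final_spec):
        """Without distribution-phase samples, the volume EBEs carry far
        less information than the clearance EBEs."""
        shr_cl, shr_v, _ = shrinkage(study_design, truth, final_spec)
        assert shr_v > shr_cl + 20.0
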