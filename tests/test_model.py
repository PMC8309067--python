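"""FOCE engine: parameter maps, likelihood oracles, and fit behaviour."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from nanopk.data import (Contrast, DoseEvent, Formulation, ObservationRow,
                         PKDataset, Route, SubjectRecord)
from nanopk.model import (OmegaMatrix, PopPKModel, SigmaValue, ThetaVector,
                          aic, eta_shrinkage, foce_marginal_neg2ll,
                          individual_params, iiv_percent,
                          subject_conditional_neg2ll)
from nanopk.simulate import Arm, StudyDesign, generate
from nanopk.structural import conc_oral

FINAL_THETA = ThetaVector(tvV=18.832, tvCL=9.167, tvTlag=0.0, tvKa=0.714,
                     tvF=0.334, dV=-0.986, dCL=-0.990, dKa=1.552, dF=0.193)


class TestIndividualParams:
    def test_reference_level_returns_typical_values(self):
        p = individual_params(FINAL_THETA, np.zeros(5), form_code=0)
        assert p.CL == pytest.approx(9.167)
        assert p.V == pytest.approx(18.832)

    def test_covariate_level_scales_linearly(self):
        p = individual_params(FINAL_THETA, np.zeros(5), form_code=1)
        assert p.CL == pytest.approx(9.167 * (1 - 0.990), rel=1e-12)
        assert p.F == pytest.approx(0.334 * 1.193, rel=1e-12)

    def test_absent_coefficients_are_identity(self):
        theta = ThetaVector(tvV=2.0, tvCL=3.0, tvKa=1.5, tvF=0.5)
        p = individual_params(theta, np.zeros(5), form_code=1)
        assert (p.V, p.CL, p.Ka, p.F) == (2.0, 3.0, 1.5, 0.5)

    def test_eta_acts_exponentially(self):
        p = individual_params(FINAL_THETA, np.array([0, 0.5, 0, 0, 0.0]), 0)
        assert p.CL == pytest.approx(9.167 * math.exp(0.5), rel=1e-12)

    def test_coefficient_destroying_positivity_rejected(self):
        theta = ThetaVector(tvV=1, tvCL=1, tvKa=1, tvF=1, dCL=-1.5)
        with pytest.raises(ValueError, match="non-positive"):
            individual_params(theta, np.zeros(5), form_code=1)


def _oral_subject(times, concs, dose=1.0, code=0):
    return SubjectRecord(
        subject_id="s", formulation=Formulation.NANOPARTICLE,
        form_code=code,
        dose_events=[DoseEvent("s", 0.0, dose, Route.ORAL)],
        observations=[ObservationRow("s", t, c)
                      for t, c in zip(times, concs)])


class TestConditionalLikelihood:
    theta = ThetaVector(tvV=1.0, tvCL=0.5, tvTlag=0.0, tvKa=2.0, tvF=0.8)

    def _exact_subject(self, n=4):
        from nanopk.structural import IndividualParams
        p = IndividualParams(V=1.0, CL=0.5, Tlag=0.0, Ka=2.0, F=0.8)
        t = np.linspace(0.5, 8, n)
        return _oral_subject(t, conc_oral(p, 1.0, t)), t

    def test_perfect_fit_leaves_only_constants(self):
        sub, t = self._exact_subject()
        val, r = subject_conditional_neg2ll(sub, self.theta, np.zeros(5),
                                            1.0)
        assert val == pytest.approx(len(t) * math.log(2 * math.pi),
                                    abs=1e-8)
        np.testing.assert_allclose(r, 0.0, atol=1e-9)

    def test_single_observation_one_sigma_off(self):
        sub, _ = self._exact_subject(n=4)
        sigma = 0.7
        # inflate one observation by exactly exp(sigma)
        obs = sub.observations
        obs[0] = ObservationRow("s", obs[0].time,
                                obs[0].conc * math.exp(sigma))
        keep = SubjectRecord("s", sub.formulation, 0, sub.dose_events,
                             [obs[0], obs[1]])
        val, _ = subject_conditional_neg2ll(keep, self.theta, np.zeros(5),
                                            sigma)
        expected = 1.0 + 2 * math.log(2 * math.pi * sigma ** 2)
        assert val == pytest.approx(expected, abs=1e-8)

    def test_matches_gaussian_density_oracle(self):
        rng = np.random.default_rng(21)
        sub, t = self._exact_subject(n=6)
        noisy = [ObservationRow("s", o.time,
                                o.conc * math.exp(rng.normal(0, 0.4)))
                 for o in sub.observations]
        sub = SubjectRecord("s", sub.formulation, 0, sub.dose_events, noisy)
        sigma = 0.4
        val, r = subject_conditional_neg2ll(sub, self.theta, np.zeros(5),
                                            sigma)
        from nanopk.structural import IndividualParams
        p = IndividualParams(V=1.0, CL=0.5, Tlag=0.0, Ka=2.0, F=0.8)
        logf = np.log(conc_oral(p, 1.0, np.array([o.time for o in noisy])))
        logy = np.log([o.conc for o in noisy])
        oracle = -2.0 * stats.norm.logpdf(logy, loc=logf, scale=sigma).sum()
        assert val == pytest.approx(oracle, abs=1e-10)


class TestMarginalLikelihood:
    def _dataset(self, seed=3, sigma=0.3, omega_cl=0.09):
        theta = ThetaVector(tvV=2.0, tvCL=1.0, tvTlag=0.0, tvKa=1.5,
                            tvF=0.6)
        omega = OmegaMatrix({"CL": omega_cl})
        design = StudyDesign(arms=(
            Arm(Formulation.NANOPARTICLE, Route.IV_BOLUS, 1.0, 4),
            Arm(Formulation.NANOPARTICLE, Route.ORAL, 1.0, 4)),
            sampling_times=(0.5, 1, 2, 4, 8, 16))
        return generate(theta, omega, SigmaValue((sigma,)), design,
                        Contrast.NP_VS_NE, seed=seed), theta, omega

    def test_zero_omega_collapses_to_conditional(self):
        ds, theta, _ = self._dataset()
        sigma = SigmaValue((0.3,))
        tiny = OmegaMatrix({"CL": 0.0})
        total, modes = foce_marginal_neg2ll(ds, theta, tiny, sigma)
        cond = sum(subject_conditional_neg2ll(s, theta, np.zeros(5),
                                              sigma)[0]
                   for s in ds.subjects)
        # the internal variance floor (1e-6) keeps the collapse from
        # being exact; the conditional value is an upper bound
        assert total == pytest.approx(cond, rel=2e-3)
        assert total <= cond + 1e-9
        assert all(np.allclose(m, 0, atol=1e-3) for m in modes.values())

    def test_linear_random_effect_has_exact_gaussian_marginal(self):
        """IIV on F enters log-linearly, so the marginal is closed-form:
        log y ~ N(log f, sigma^2 + omega^2_F) per observation subject."""
        theta = ThetaVector(tvV=1.0, tvCL=0.5, tvTlag=0.0, tvKa=2.0,
                            tvF=0.8)
        from nanopk.structural import IndividualParams
        p = IndividualParams(V=1.0, CL=0.5, Tlag=0.0, Ka=2.0, F=0.8)
        t, y = 2.0, 150.0
        sub = _oral_subject([t, 9.0], [y, 1.0])
        # single-observation subject keeps the integral 1-dimensional
        sub.observations = sub.observations[:1]
        sigma2, omega2 = 0.25, 0.49
        total, _ = foce_marginal_neg2ll(
            PKDataset([sub], Contrast.NP_VS_NE), theta,
            OmegaMatrix({"F": omega2}), SigmaValue((math.sqrt(sigma2),)))
        logf = math.log(conc_oral(p, 1.0, t))
        closed = -2 * stats.norm.logpdf(math.log(y), loc=logf,
                                        scale=math.sqrt(sigma2 + omega2))
        assert total == pytest.approx(closed, rel=1e-8)

    def test_against_quadrature_oracle_one_effect(self):
        """FOCE approximation within 1% of exact 1-D integration over
        eta_CL, which enters the prediction nonlinearly."""
        ds, theta, omega = self._dataset(seed=5, sigma=0.3, omega_cl=0.04)
        sigma = SigmaValue((0.3,))
        total, _ = foce_marginal_neg2ll(ds, theta, omega, sigma)
        w = math.sqrt(0.04)
        oracle = 0.0
        for s in ds.subjects:
            def integrand(eta):
                cond, _ = subject_conditional_neg2ll(
                    s, theta, np.array([0, eta, 0, 0, 0.0]), sigma)
                return math.exp(-0.5 * cond) * stats.norm.pdf(eta, 0, w)
            val, _ = integrate.quad(integrand, -8 * w, 8 * w, limit=200)
            oracle += -2.0 * math.log(val)
        assert total == pytest.approx(oracle, rel=0.01)

    def test_truth_beats_perturbed_clearance(self):
        ds, theta, omega = self._dataset(seed=9)
        sigma = SigmaValue((0.3,))
        base, _ = foce_marginal_neg2ll(ds, theta, omega, sigma)
        rng = np.random.default_rng(1)
        for _ in range(20):
            factor = rng.choice([0.5, 2.0]) * rng.uniform(0.9, 1.1)
            worse = ThetaVector(tvV=theta.tvV, tvCL=theta.tvCL * factor,
                                tvTlag=0.0, tvKa=theta.tvKa, tvF=theta.tvF)
            alt, _ = foce_marginal_neg2ll(ds, worse, omega, sigma)
            assert alt > base


class TestFitBehaviour:
    def _noiseless_dataset(self):
        theta = ThetaVector(tvV=2.0, tvCL=1.0, tvTlag=0.0, tvKa=1.5,
                            tvF=0.6)
        design = StudyDesign(arms=(
            Arm(Formulation.NANOPARTICLE, Route.IV_BOLUS, 1.0, 2),
            Arm(Formulation.NANOPARTICLE, Route.ORAL, 1.0, 2)),
            sampling_times=(0.25, 0.5, 1, 2, 4, 8, 16))
        return generate(theta, OmegaMatrix({}), SigmaValue((0.0,)), design,
                        Contrast.NP_VS_NE, seed=0), theta

    def test_noiseless_identifiable_limit_recovers_typical_values(self):
        ds, theta = self._noiseless_dataset()
        model = PopPKModel(ds, covariates=(), iiv=("CL",))
        res = model.fit(seed=0, compute_se=False, ftol=1e-12)
        for p in ("V", "CL", "Ka", "F"):
            assert res.estimates[f"tv{p}"] == pytest.approx(
                theta.tv(p), rel=1e-3)

    def test_multi_start_stability(self):
        """Dispersed initial guesses land on the same optimum."""
        theta = ThetaVector(tvV=2.0, tvCL=1.0, tvTlag=0.0, tvKa=1.5,
                            tvF=0.6)
        design = StudyDesign(arms=(
            Arm(Formulation.NANOPARTICLE, Route.IV_BOLUS, 1.0, 3),
            Arm(Formulation.NANOPARTICLE, Route.ORAL, 1.0, 3)),
            sampling_times=(0.25, 0.5, 1, 2, 4, 8, 16))
        ds = generate(theta, OmegaMatrix({"CL": 0.04}), SigmaValue((0.25,)),
                      design, Contrast.NP_VS_NE, seed=6)
        rng = np.random.default_rng(4)
        vals = []
        for k in range(5):
            jitter = math.exp(rng.normal(0, 0.4))
            start = ThetaVector(tvV=2.0 * jitter, tvCL=1.0 / jitter,
                                tvTlag=1e-3, tvKa=1.5 * jitter,
                                tvF=0.6 / jitter)
            # n_starts > 1 guards against the absorption/elimination
            # flip-flop optimum that extreme starts can fall into
            res = PopPKModel(ds, covariates=(), iiv=("CL",)).fit(
                start=start, seed=k, n_starts=3, compute_se=False)
            vals.append(res.neg2ll)
        assert max(vals) - min(vals) < 0.01

    def test_fit_result_identities(self, fit_final_reduced):
        fr = fit_final_reduced.fit_result
        assert fr.aic == pytest.approx(fr.neg2ll + 2 * fr.n_params,
                                       abs=1e-9)
        assert fr.ofv == fr.neg2ll
        for p, val in fr.iiv_percent.items():
            assert val == pytest.approx(
                100 * math.sqrt(fr.omega.omega2[p]), abs=1e-9)
        for name, se in fr.se.items():
            est = fr.estimates[name]
            if abs(est) > 1e-12 and np.isfinite(fr.rse_percent[name]):
                assert fr.rse_percent[name] == pytest.approx(
                    100 * se / abs(est), rel=1e-9)

    def test_nested_model_monotonicity(self, sim_dataset, fit_final,
                                       fit_final_reduced):
        """More parameters never raise the minimized -2LL materially."""
        assert (fit_final.neg2ll
                <= fit_final_reduced.neg2ll + 0.5)


class TestSummaries:
    def test_aic_arithmetic(self):
        assert aic(759.13, 11) == pytest.approx(781.13)
        assert aic(1505.72, 11) == pytest.approx(1527.72)
        assert aic(0.0, 0) == 0.0

    def test_eta_shrinkage_limits(self):
        omega = OmegaMatrix({"CL": 0.25})
        spread = {f"s{i}": np.array([0, e, 0, 0, 0.0])
                  for i, e in enumerate([-0.5, 0.0, 0.5])}
        assert eta_shrinkage(spread, omega)["CL"] == pytest.approx(0.0)
        collapsed = {f"s{i}": np.zeros(5) for i in range(3)}
        assert eta_shrinkage(collapsed, omega)["CL"] == pytest.approx(100.0)

    def test_iiv_percent_from_published_variances(self):
        omega = OmegaMatrix({"CL": 0.338, "F": 0.386, "V": 0.0})
        out = iiv_percent(omega)
        assert out["CL"] == pytest.approx(58.14, abs=0.02)
        assert out["F"] == pytest.approx(62.13, abs=0.02)
        assert out["V"] == 0.0
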