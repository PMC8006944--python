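import numpy as np
import pytest
from scipy.optimize import minimize

from ocmm.core import FastOCMMSimulator, KineticParams, SecretionParams, simulate_ocmm
from ocmm.identify import (
    PARAM_NAMES,
    ErrorModel,
    FitConfig,
    FlatPrior,
    LogNormalPrior,
    PriorSpec,
    build_prior,
    fit_subject,
    neg_log_posterior,
    parameter_precision,
)
from ocmm.io import SubjectRecord
from ocmm.van_cauter import vc_kinetics
from tests.conftest import OGTT_SCHEDULE

FLAT_SPEC = PriorSpec(marginals={n: FlatPrior() for n in PARAM_NAMES})


def params_vector(truth):
    return np.array([truth[n] for n in PARAM_NAMES])


class TestNegLogPosterior:
    def test_perfect_fit_flat_priors_is_zero(self, noise_free_subject, phh_signal):
        record, truth = noise_free_subject
        # regenerate data with the same discretization the likelihood uses
        kin = KineticParams(truth["k01"], truth["k12"], truth["k21"])
        sec = SecretionParams(truth["k_d"], truth["alpha"], truth["beta"], h=record.glucose_basal)
        cp = simulate_ocmm(kin, sec, phh_signal, record.times, record.cp_basal, method="lti")
        rec = SubjectRecord("Z", record.demographics, "OGTT", record.times, record.glucose, cp)
        val = neg_log_posterior(
            params_vector(truth), rec, phh_signal, FLAT_SPEC, ErrorModel(0.05)
        )
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_prior_at_median_adds_nothing(self, noise_free_subject, phh_signal):
        record, truth = noise_free_subject
        p = params_vector(truth)
        flat_val = neg_log_posterior(p, record, phh_signal, FLAT_SPEC, ErrorModel(0.05))
        with_prior = PriorSpec(
            marginals={
                **{n: FlatPrior() for n in PARAM_NAMES if n != "alpha"},
                "alpha": LogNormalPrior(median=truth["alpha"], gcv=0.5),
            }
        )
        val = neg_log_posterior(p, record, phh_signal, with_prior, ErrorModel(0.05))
        assert val == pytest.approx(flat_val, abs=1e-12)

    def test_weighted_residual_arithmetic(self, noise_free_subject, phh_signal):
        """The likelihood term is half the sum of squared sigma-scaled residuals."""
        record, truth = noise_free_subject
        kin = KineticParams(truth["k01"], truth["k12"], truth["k21"])
        sec = SecretionParams(truth["k_d"], truth["alpha"], truth["beta"], h=record.glucose_basal)
        yhat = record.cp_basal + FastOCMMSimulator(
            phh_signal, record.times, record.glucose_basal
        ).cp1(kin, sec)
        rng = np.random.default_rng(1)
        delta = rng.normal(0.0, 30.0, yhat.size)
        delta[0] = 0.0  # the t=0 sample defines the basal and has zero residual
        y = yhat + delta
        rec = SubjectRecord("Z", record.demographics, "OGTT", record.times, record.glucose, y)
        err = ErrorModel(0.05)
        expected = 0.5 * np.sum((delta / (0.05 * y)) ** 2)
        val = neg_log_posterior(params_vector(truth), rec, phh_signal, FLAT_SPEC, err)
        assert val == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_parameters_rejected(self, noise_free_subject, phh_signal):
        record, truth = noise_free_subject
        p = params_vector(truth)
        p[0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            neg_log_posterior(p, record, phh_signal, FLAT_SPEC, ErrorModel(0.05))


class TestMapRecovery:
    def test_flat_prior_map_equals_truth(self, noise_free_subject, phh_signal):
        """With flat priors and noise-free model-generated data the posterior
        minimum sits at the generating parameters (recovered to 1e-3)."""
        record, truth = noise_free_subject
        kin = KineticParams(truth["k01"], truth["k12"], truth["k21"])
        sec = SecretionParams(truth["k_d"], truth["alpha"], truth["beta"], h=record.glucose_basal)
        cp = simulate_ocmm(kin, sec, phh_signal, record.times, record.cp_basal, method="lti")
        rec = SubjectRecord("Z", record.demographics, "OGTT", record.times, record.glucose, cp)
        sim = FastOCMMSimulator(phh_signal, rec.times, rec.glucose_basal)
        err = ErrorModel(0.05)

        def f(z):
            return neg_log_posterior(np.exp(z), rec, phh_signal, FLAT_SPEC, err, fine_dt=1.0)

        p_true = params_vector(truth)
        rng = np.random.default_rng(0)
        z0 = np.log(p_true) + rng.uniform(-0.2, 0.2, 6)
        res = minimize(f, z0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12})
        res = minimize(f, res.x, method="Nelder-Mead",
                       options={"maxfev": 20000, "xatol": 1e-12, "fatol": 1e-16})
        np.testing.assert_allclose(np.exp(res.x), p_true, rtol=1e-3)

    def test_vc_self_consistency(self, noise_free_subject, phh_signal):
        """Kinetics fixed at truth: secretion parameters recovered within 1%
        when the true glucose curve is supplied as the error-free input."""
        record, truth = noise_free_subject
        fit = fit_subject(record, "VC", config=FitConfig(n_starts=2), signal=phh_signal)
        for name in ("k_d", "alpha", "beta"):
            assert fit.estimates[name] == pytest.approx(truth[name], rel=0.01)
        assert fit.converged
        assert fit.objective <= fit.objective_initial

    def test_db_recovers_inflated_clearance(self, phh_signal, demo_normal):
        """15% faster clearance than the population prior center is recovered
        within 2% from noise-free data."""
        vc = vc_kinetics(demo_normal)
        kin = KineticParams(vc.k01 * 1.15, vc.k12, vc.k21)
        sec = SecretionParams(k_d=3750.0, alpha=0.05, beta=16.0, h=phh_signal.basal)
        cp = simulate_ocmm(kin, sec, phh_signal, OGTT_SCHEDULE, 340.0, method="rk45")
        rec = SubjectRecord(
            "I15", demo_normal, "OGTT", OGTT_SCHEDULE, phh_signal.sample(OGTT_SCHEDULE), cp
        )
        fit = fit_subject(rec, "DB", config=FitConfig(n_starts=2), signal=phh_signal)
        assert fit.estimates["k01"] == pytest.approx(kin.k01, rel=0.02)

    def test_db_with_tight_kinetic_priors_reproduces_vc(self, noise_free_subject):
        """As the kinetic prior spread shrinks to zero the DB fit collapses
        onto the VC fit (kinetics pinned at the population prediction)."""
        record, truth = noise_free_subject
        vc_fit = fit_subject(record, "VC", config=FitConfig(n_starts=2))
        db_fit = fit_subject(
            record, "DB", config=FitConfig(n_starts=2, kinetic_prior_gcv=1e-4)
        )
        vc = vc_kinetics(record.demographics)
        for name, ref in (("k01", vc.k01), ("k12", vc.k12), ("k21", vc.k21)):
            assert db_fit.estimates[name] == pytest.approx(ref, rel=1e-3)
        for name in ("k_d", "alpha", "beta"):
            assert db_fit.estimates[name] == pytest.approx(vc_fit.estimates[name], rel=0.01)

    def test_multistart_spread_small_on_well_conditioned_subject(self, noise_free_subject):
        record, _ = noise_free_subject
        fit = fit_subject(record, "VC", config=FitConfig(n_starts=4))
        spread = fit.start_estimates.std(axis=0) / fit.start_estimates.mean(axis=0)
        assert np.all(spread < 0.01)

    def test_phh_requires_population(self, noise_free_subject):
        record, _ = noise_free_subject
        with pytest.raises(ValueError, match="population"):
            fit_subject(record, "PHH")

    def test_unknown_approach_rejected(self, noise_free_subject):
        record, _ = noise_free_subject
        with pytest.raises(ValueError, match="approach"):
            build_prior(record, "ml", FitConfig())


class TestPrecision:
    def test_fixed_parameters_have_no_cv(self, noise_free_subject):
        record, _ = noise_free_subject
        fit = fit_subject(record, "VC", config=FitConfig(n_starts=2))
        assert set(fit.cv_percent) == {"k_d", "alpha", "beta"}

    def test_doubling_sigma_doubles_likelihood_cv(self, noise_free_subject):
        """With (effectively) flat priors the posterior is likelihood-only, so
        doubling the measurement SD doubles every parameter CV."""
        record, _ = noise_free_subject
        cfg = FitConfig(n_starts=2, alpha_prior_gcv=1e8)
        fit = fit_subject(record, "VC", config=cfg, err=ErrorModel(0.04))
        cv1 = parameter_precision(fit, record, err=ErrorModel(0.04), config=cfg)
        cv2 = parameter_precision(fit, record, err=ErrorModel(0.08), config=cfg)
        for name in cv1:
            assert cv2[name] == pytest.approx(2.0 * cv1[name], rel=1e-3)

    def test_db_cvs_have_plausible_magnitude(self, phh_signal, demo_normal):
        """DB-estimated parameters carry tens-of-percent precision at 5% noise."""
        vc = vc_kinetics(demo_normal)
        kin = KineticParams(vc.k01 * 1.15, vc.k12 * 1.1, vc.k21 * 1.2)
        sec = SecretionParams(k_d=3750.0, alpha=0.03, beta=16.0, h=phh_signal.basal)
        cp = simulate_ocmm(kin, sec, phh_signal, OGTT_SCHEDULE, 340.0, method="rk45")
        rng = np.random.default_rng(2)
        cp_noisy = cp * (1 + 0.05 * rng.normal(size=cp.size))
        rec = SubjectRecord(
            "P", demo_normal, "OGTT", OGTT_SCHEDULE, phh_signal.sample(OGTT_SCHEDULE), cp_noisy
        )
        fit = fit_subject(rec, "DB", config=FitConfig(n_starts=2), signal=phh_signal)
        cvs = np.array(list(fit.cv_percent.values()))
        assert np.all(np.isfinite(cvs))
        assert 2.0 < np.median(cvs) < 80.0
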