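"""Population model: parameter mapping, CV conversions, censored likelihood."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from rifpk.covariates import CovariateEffect
from rifpk.popmodel import (IndividualEffects, PopulationModel, cv_to_omega,
                            draw_effects, individual_params, obs_loglik,
                            omega_to_cv, residual_sd)

THETA = {"Tlag": 0.340, "Tk0": 0.470, "V": 36.2, "Vmax": 190.0, "Km": 20.1}


def _ffm_model(**kw):
    defaults = dict(
        theta=THETA,
        covariate_effects=(
            CovariateEffect("V", "FFM", "power", beta=1.0, reference=50.0),
            CovariateEffect("Vmax", "FFM", "power", beta=0.75, reference=50.0),
        ),
        iiv_cv={"Vmax": 18.5},
        iov_cv={"Tlag": 39.0, "Tk0": 65.5, "V": 14.9, "Vmax": 9.39},
        corr_iov_tlag_tk0=0.410,
        error_a=0.060, error_b=0.110,
    )
    defaults.update(kw)
    return PopulationModel(**defaults)


ZERO_EFF = IndividualEffects(eta={}, kappa=[{}, {}])


class TestIndividualParams:
    cov_ref = {"FFM": 50.0, "sex": "female"}

    def test_identity_at_mode(self):
        p = individual_params(_ffm_model(), self.cov_ref, ZERO_EFF, 1)
        for name, val in THETA.items():
            assert getattr(p, name) == pytest.approx(val)

    def test_log_scale_additivity(self):
        eff = IndividualEffects(eta={"Vmax": math.log(2.0)}, kappa=[{}, {}])
        p = individual_params(_ffm_model(), self.cov_ref, eff, 2)
        assert p.Vmax == pytest.approx(2 * THETA["Vmax"])
        assert p.V == pytest.approx(THETA["V"])

    def test_ffm_doubling(self):
        p = individual_params(_ffm_model(), {"FFM": 100.0}, ZERO_EFF, 1)
        assert p.V == pytest.approx(72.4)
        assert p.Vmax == pytest.approx(190.0 * 2**0.75)

    def test_occasion_effects_are_occasion_specific(self):
        eff = IndividualEffects(eta={}, kappa=[{"Tk0": 0.3}, {}])
        p1 = individual_params(_ffm_model(), self.cov_ref, eff, 1)
        p2 = individual_params(_ffm_model(), self.cov_ref, eff, 2)
        assert p1.Tk0 == pytest.approx(THETA["Tk0"] * math.exp(0.3))
        assert p2.Tk0 == pytest.approx(THETA["Tk0"])


class TestCVConversions:
    def test_zero(self):
        assert cv_to_omega(0.0) == 0.0

    def test_published_iiv_value(self):
        # 39 CV% on the log-normal scale
        assert cv_to_omega(39.0) == pytest.approx(
            math.sqrt(math.log(1 + 0.39**2)), rel=1e-12)
        assert cv_to_omega(39.0) == pytest.approx(0.37632, abs=5e-5)

    @pytest.mark.parametrize("cv", [1.0, 18.5, 39.0, 66.9])
    def test_round_trip(self, cv):
        assert omega_to_cv(cv_to_omega(cv)) == pytest.approx(cv, rel=1e-12)

    def test_approximate_convention(self):
        assert cv_to_omega(30.0, exact=False) == pytest.approx(0.30)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_to_omega(-1.0)


class TestResidualSD:
    def test_additive_only_at_zero_pred(self):
        assert residual_sd(0.0, 0.060, 0.110) == pytest.approx(0.060)

    def test_combined_value(self):
        assert residual_sd(10.0, 0.060, 0.110) == pytest.approx(1.16)

    def test_degenerate_constant_model(self):
        assert residual_sd(10.0, 0.5, 0.0) == pytest.approx(0.5)

    def test_combined2_convention(self):
        assert residual_sd(10.0, 0.06, 0.11,
                           "combined2") == pytest.approx(
            math.hypot(0.06, 1.1))


class TestObsLoglik:
    def test_gaussian_mode(self):
        g = residual_sd(5.0, 0.06, 0.11)
        assert obs_loglik(5.0, 0, 5.0, 0.06, 0.11) == pytest.approx(
            math.log(1.0 / (g * math.sqrt(2 * math.pi))))

    def test_censored_at_zero_prediction(self):
        # prediction 0: half the Gaussian mass lies below 0, so the interval
        # [0, LLOQ) holds Phi(LLOQ/g) - 1/2
        a = 0.06
        val = obs_loglik(0.1, 1, 0.0, a, 0.11, lloq=0.1)
        assert val == pytest.approx(math.log(norm.cdf(0.1 / a) - 0.5))

    def test_censored_matches_quadrature(self):
        """Interval mass on [0, LLOQ) against numeric quadrature (1e-8)."""
        pred, g, lloq = 5.0, 0.61, 0.1
        b = (g - 0.06) / pred
        mass, _err = quad(lambda x: norm.pdf(x, loc=pred, scale=g), 0.0, lloq,
                          epsabs=1e-16, epsrel=1e-12)
        assert obs_loglik(lloq, 1, pred, 0.06, b, lloq=lloq) == pytest.approx(
            math.log(mass), abs=1e-8)

    def test_fine_partition_consistency(self):
        """Summing observed-likelihood mass over a fine partition of
        [0, LLOQ) converges to the censored contribution."""
        pred, a, b, lloq = 0.3, 0.06, 0.11, 0.1
        g = residual_sd(pred, a, b)
        xs = np.linspace(0, lloq, 4001)
        riemann = np.trapezoid(norm.pdf(xs, loc=pred, scale=g), xs)
        assert obs_loglik(lloq, 1, pred, a, b, lloq=lloq) == pytest.approx(
            math.log(riemann), abs=1e-6)

    def test_underflow_floored(self):
        val = obs_loglik(0.1, 1, 1e4, 0.06, 0.0, lloq=0.1, log_floor=-500.0)
        assert val == pytest.approx(-500.0)


class TestRandomEffectSampling:
    def test_lognormal_cv_recovered(self):
        """Empirical CV of simulated V matches the declared CV within 2%."""
        model = _ffm_model(iiv_cv={"V": 24.4, "Vmax": 18.5})
        rng = np.random.default_rng(123)
        eta, _ = draw_effects(model, 100_000, 1, rng)
        v = THETA["V"] * np.exp(eta[:, 2])
        emp_cv = 100.0 * v.std() / v.mean()
        assert emp_cv == pytest.approx(24.4, rel=0.02)

    def test_iov_correlation_recovered(self):
        """Empirical corr(kappa_Tlag, kappa_Tk0) matches rho within 0.02."""
        model = _ffm_model()
        rng = np.random.default_rng(456)
        _, kappa = draw_effects(model, 100_000, 1, rng)
        r = np.corrcoef(kappa[:, 0, 0], kappa[:, 0, 1])[0, 1]
        assert r == pytest.approx(0.410, abs=0.02)

    def test_kappa_independent_across_occasions(self):
        model = _ffm_model()
        rng = np.random.default_rng(789)
        _, kappa = draw_effects(model, 50_000, 2, rng)
        r = np.corrcoef(kappa[:, 0, 1], kappa[:, 1, 1])[0, 1]
        assert abs(r) < 0.02


class TestModelValidation:
    def test_km_random_effect_rejected(self):
        with pytest.raises(ValueError, match="Km"):
            _ffm_model(iov_cv={"Km": 10.0})

    def test_error_params_not_both_zero(self):
        with pytest.raises(ValueError):
            _ffm_model(error_a=0.0, error_b=0.0)

    def test_correlation_bounds(self):
        with pytest.raises(ValueError):
            _ffm_model(corr_iov_tlag_tk0=1.0)

    def test_sigma_structure(self):
        model = _ffm_model()
        sig = model.sigma(2)
        om2 = cv_to_omega(18.5) ** 2
        g_tlag = cv_to_omega(39.0)
        g_tk0 = cv_to_omega(65.5)
        # cross-occasion block carries only the IIV part (Vmax here)
        assert sig[3, 7] == pytest.approx(om2)
        assert sig[0, 4] == pytest.approx(0.0, abs=1e-9)
        # within-occasion Tlag-Tk0 coupling equals rho*g1*g2
        assert sig[0, 1] == pytest.approx(0.410 * g_tlag * g_tk0)
        np.testing.assert_allclose(sig, sig.T)
        assert np.all(np.linalg.eigvalsh(sig) > 0)
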