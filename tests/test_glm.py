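import numpy as np
import pytest
import statsmodels.api as sm

from difreduce.glm import (
    MeasurementModel,
    RankDeficiencyError,
    SeparationError,
    fisher_information_target,
    fit_item,
    loglik,
)


def test_loglik_logit_all_zero_coefficients_gives_log_half_per_respondent():
    m = MeasurementModel(link="logit", beta0=0.0, beta_theta=0.0)
    y = np.array([0.0, 1.0, 1.0, 0.0])
    theta = np.array([0.3, -0.1, 2.0, 0.5])
    assert loglik(m, y, theta) == pytest.approx(4 * np.log(0.5), abs=1e-12)


def test_loglik_identity_zero_residuals():
    theta = np.linspace(-2, 2, 9)
    m = MeasurementModel(link="identity", beta0=0.0, beta_theta=1.0, sigma2=1.0)
    assert loglik(m, theta.copy(), theta) == pytest.approx(
        -0.5 * len(theta) * np.log(2 * np.pi), abs=1e-12
    )


def test_loglik_matches_per_respondent_bernoulli_summation(rng):
    # independent oracle: term-by-term Bernoulli log-pmf in a python loop
    n = 20
    theta = rng.standard_normal(n)
    eta = rng.standard_normal(n)
    y = (rng.random(n) < 0.5).astype(float)
    m = MeasurementModel(link="logit", beta0=0.3, beta_theta=1.2, beta_eta=0.5)
    expected = 0.0
    for i in range(n):
        p = 1.0 / (1.0 + np.exp(-(0.3 + 1.2 * theta[i] + 0.5 * eta[i])))
        expected += np.log(p if y[i] == 1.0 else 1.0 - p)
    assert loglik(m, y, theta, eta=eta) == pytest.approx(expected, rel=1e-12)


def test_loglik_rejects_nonbinary_response_naming_index():
    m = MeasurementModel(link="logit", beta0=0.0, beta_theta=1.0)
    y = np.array([0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="index 2"):
        loglik(m, y, np.zeros(3))


def test_fit_identity_recovers_noiseless_coefficients(rng):
    theta = rng.standard_normal(50)
    y = 0.5 + 1.0 * theta
    m = fit_item("identity", y, theta)
    assert m.beta0 == pytest.approx(0.5, abs=1e-10)
    assert m.beta_theta == pytest.approx(1.0, abs=1e-10)


def test_fit_logit_matches_statsmodels_mle(rng):
    n = 200
    theta = rng.standard_normal(n)
    eta = rng.standard_normal(n)
    lp = 0.0 + 1.0 * theta + 0.8 * eta
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    ours = fit_item("logit", y, theta, eta=eta)
    X = np.column_stack([np.ones(n), theta, eta])
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(
        [ours.beta0, ours.beta_theta, ours.beta_eta], ref.params, atol=1e-5
    )
    assert ours.loglik_at_fit == pytest.approx(ref.llf, abs=1e-6)


def test_fit_probit_matches_statsmodels(rng):
    n = 300
    theta = rng.standard_normal(n)
    from scipy.special import ndtr
    y = (rng.random(n) < ndtr(0.2 + 0.9 * theta)).astype(float)
    ours = fit_item("probit", y, theta)
    ref = sm.Probit(y, np.column_stack([np.ones(n), theta])).fit(disp=0)
    np.testing.assert_allclose([ours.beta0, ours.beta_theta], ref.params, atol=1e-5)


def test_constant_group_column_raises_rank_deficiency(rng):
    theta = rng.standard_normal(30)
    y = theta + 0.1 * rng.standard_normal(30)
    with pytest.raises(RankDeficiencyError, match="z0"):
        fit_item("identity", y, theta, z=np.ones(30))


def test_perfect_separation_raises_rather_than_diverging(rng):
    theta = rng.standard_normal(100)
    y = (theta > 0).astype(float)
    with pytest.raises(SeparationError):
        fit_item("logit", y, theta)


def test_loglik_at_fit_recomputable_from_stored_coefficients(rng):
    n = 150
    theta = rng.standard_normal(n)
    z = (rng.random(n) < 0.5).astype(float)
    for link, y in (
        ("identity", theta + 0.3 * z + 0.5 * rng.standard_normal(n)),
        ("logit", (rng.random(n) < 1 / (1 + np.exp(-theta))).astype(float)),
    ):
        m = fit_item(link, y, theta, z=z)
        assert m.loglik_at_fit == pytest.approx(
            loglik(m, y, theta, z=z), abs=1e-8
        )


def test_fit_loglik_dominates_perturbed_coefficients(rng):
    n = 200
    theta = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + theta)))).astype(float)
    m = fit_item("logit", y, theta)
    for d0, d1 in [(0.1, 0.0), (0.0, -0.1), (0.05, 0.05)]:
        worse = MeasurementModel(link="logit", beta0=m.beta0 + d0,
                                 beta_theta=m.beta_theta + d1)
        assert m.loglik_at_fit >= loglik(worse, y, theta)


def test_nesting_full_model_loglik_at_least_reduced(rng):
    n = 250
    theta = rng.standard_normal(n)
    z = (rng.random(n) < 0.5).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(theta + 0.4 * z)))).astype(float)
    red = fit_item("logit", y, theta)
    full = fit_item("logit", y, theta, z=z)
    assert full.loglik_at_fit >= red.loglik_at_fit


def test_fisher_information_closed_forms():
    m_lin = MeasurementModel(link="identity", beta0=0.0, beta_theta=2.0,
                             sigma2=4.0, loglik_at_fit=0.0)
    assert fisher_information_target(m_lin) == pytest.approx(1.0)
    m_log = MeasurementModel(link="logit", beta0=0.0, beta_theta=1.0,
                             loglik_at_fit=0.0)
    theta = np.zeros(10)  # p = 0.5 everywhere: maximal Bernoulli variance
    assert fisher_information_target(m_log, theta) == pytest.approx(0.25)


def test_fisher_information_matches_finite_difference_curvature(rng):
    # -E d2 loglik / d theta-shift^2 via central differences, per respondent
    n = 50
    theta = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 1.1 * theta)))).astype(float)
    m = fit_item("logit", y, theta)
    fi = fisher_information_target(m, theta)
    from scipy.special import expit
    h = 1e-5

    def expected_ll(t_shift):
        # expectation under the fitted model of the shifted log-likelihood
        p_fit = expit(m.beta0 + m.beta_theta * theta)
        lp = m.beta0 + m.beta_theta * (theta + t_shift)
        return np.mean(p_fit * lp - np.logaddexp(0.0, lp))

    curv = (expected_ll(h) - 2 * expected_ll(0.0) + expected_ll(-h)) / h**2
    assert fi == pytest.approx(-curv, rel=1e-4)


def test_fisher_information_requires_fit_and_covariates():
    m = MeasurementModel(link="logit", beta0=0.0, beta_theta=1.0)
    with pytest.raises(ValueError, match="fitted"):
        fisher_information_target(m, np.zeros(3))


def test_nonuniform_interaction_coefficient_is_fit(rng):
    n = 3000
    theta = rng.standard_normal(n)
    z = (rng.random(n) < 0.5).astype(float)
    lp = 0.1 + 1.0 * theta + 0.5 * z + 0.6 * theta * z
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    m = fit_item("logit", y, theta, z=z, interactions=True)
    assert m.beta_theta_z is not None
    assert m.beta_theta_z[0] == pytest.approx(0.6, abs=0.2)
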