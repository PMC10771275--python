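"""Mixed-effects machinery: Laplace exactness, quadrature oracle, fitting,
information criteria and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

import meningrowth as mg
from meningrowth.models import get_model, mean_gradient, mean_response
from meningrowth.nlme import (
    CovariateDesign,
    default_re_spec,
    marginal_loglik_laplace,
    marginal_loglik_quadrature,
)
from meningrowth.simulate import SimulationConfig, simulate_cohort

from conftest import make_cohort

GOMPERTZ_THETA = np.array([math.log(2.6) + 1.0, math.log(2.6), 0.02])
GOMPERTZ_PSI = np.array([[1.21, 1.21], [1.21, 1.46]])  # (log_v0, log_k)
SIGMA2 = 0.09**2


def closed_form_loglik(model_name, re_params, cohort, theta, psi, sigma2):
    """Independent oracle: exact Gaussian marginal for models linear in b.

    When the mean is mu0 + Z b the marginal is N(mu0, Z Psi Z' + sigma2 I),
    evaluated here directly with scipy's multivariate normal.
    """
    model = get_model(model_name)
    re_idx = [model.param_index(p) for p in re_params]
    total = 0.0
    for patient in cohort:
        t = patient.times
        y = np.log(patient.volumes) if model.response_scale == "log_volume" \
            else patient.volumes
        mu = mean_response(model, theta, t)
        Z = mean_gradient(model, theta, t)[:, re_idx]
        V = Z @ psi @ Z.T + sigma2 * np.eye(t.size)
        total += multivariate_normal.logpdf(y, mu, V)
    return total


@pytest.fixture(scope="module")
def gompertz_cohort_10():
    cohort, _ = simulate_cohort(SimulationConfig(n_patients=10, seed=3))
    return cohort


class TestLaplace:
    def test_exact_for_linear_random_intercept(self, rng):
        """Laplace equals the closed-form LMM likelihood (Gaussian integrand)."""
        series = {}
        for i in range(5):
            t = np.array([0.0, 8.0, 16.0, 24.0])
            v = np.maximum(3.0 + rng.normal(0, 1.2) + 0.05 * t
                           + rng.normal(0, 0.3, 4), 0.05)
            series[f"P{i}"] = (t, v)
        cohort = make_cohort(series)
        spec = mg.RandomEffectSpec(("intercept",))
        theta = np.array([3.0, 0.05])
        psi = np.array([[1.5]])
        ll = marginal_loglik_laplace("linear", spec, cohort, theta, psi, 0.09)
        ll_cf = closed_form_loglik("linear", ("intercept",), cohort, theta, psi, 0.09)
        assert ll == pytest.approx(ll_cf, abs=1e-6)

    def test_exact_for_gompertz_size_random_effects(self, gompertz_cohort_10):
        spec = mg.RandomEffectSpec(("log_v0", "log_k"))
        ll = marginal_loglik_laplace(
            "gompertz", spec, gompertz_cohort_10, GOMPERTZ_THETA, GOMPERTZ_PSI, SIGMA2
        )
        ll_cf = closed_form_loglik(
            "gompertz", ("log_v0", "log_k"), gompertz_cohort_10,
            GOMPERTZ_THETA, GOMPERTZ_PSI, SIGMA2,
        )
        assert ll == pytest.approx(ll_cf, abs=1e-8)

    def test_zero_psi_degenerates_to_fixed_effects_likelihood(
        self, gompertz_cohort_10
    ):
        spec = mg.RandomEffectSpec(("log_v0", "log_k"))
        ll0 = marginal_loglik_laplace(
            "gompertz", spec, gompertz_cohort_10, GOMPERTZ_THETA,
            np.zeros((2, 2)), SIGMA2,
        )
        direct = 0.0
        for p in gompertz_cohort_10:
            mu = mean_response("gompertz", GOMPERTZ_THETA, p.times)
            direct += float(
                np.sum(norm.logpdf(np.log(p.volumes), mu, math.sqrt(SIGMA2)))
            )
        assert ll0 == pytest.approx(direct, abs=1e-9)
        # continuity: a tiny psi approaches the degenerate value
        ll_eps = marginal_loglik_laplace(
            "gompertz", spec, gompertz_cohort_10, GOMPERTZ_THETA,
            1e-10 * np.eye(2), SIGMA2,
        )
        assert ll_eps == pytest.approx(ll0, abs=1e-3)


class TestQuadrature:
    def test_gaussian_case_matches_closed_form(self, gompertz_cohort_10):
        spec = mg.RandomEffectSpec(("log_v0", "log_k"))
        ll_q = marginal_loglik_quadrature(
            "gompertz", spec, gompertz_cohort_10, GOMPERTZ_THETA, GOMPERTZ_PSI,
            SIGMA2, n_nodes=21,
        )
        ll_cf = closed_form_loglik(
            "gompertz", ("log_v0", "log_k"), gompertz_cohort_10,
            GOMPERTZ_THETA, GOMPERTZ_PSI, SIGMA2,
        )
        assert ll_q == pytest.approx(ll_cf, abs=1e-8)

    def test_radial_laplace_close_to_quadrature(self):
        """Genuinely nonlinear random effects: Laplace is approximate but close."""
        cohort, _ = simulate_cohort(
            SimulationConfig(n_patients=10, model="radial", seed=3)
        )
        spec = mg.RandomEffectSpec(("r0", "alpha"))
        theta = np.array([0.853, 0.005])
        psi = np.array([[0.09, 0.0], [0.0, 4e-6]])
        ll_lap = marginal_loglik_laplace("radial", spec, cohort, theta, psi, SIGMA2)
        ll_q = marginal_loglik_quadrature(
            "radial", spec, cohort, theta, psi, SIGMA2, n_nodes=41
        )
        assert abs(ll_lap - ll_q) < 0.05  # ~0.005 per patient

    def test_rejects_more_than_two_random_effects(self, gompertz_cohort_10):
        spec = mg.RandomEffectSpec(("log_k", "log_v0", "alpha"))
        with pytest.raises(ValueError, match="at most 2"):
            marginal_loglik_quadrature(
                "gompertz", spec, gompertz_cohort_10, GOMPERTZ_THETA,
                np.eye(3), SIGMA2,
            )

    def test_monte_carlo_agreement_single_random_effect(self, rng):
        """Plain Monte-Carlo integration agrees within 3 MC standard errors."""
        series = {
            f"P{i}": (
                np.array([0.0, 10.0, 20.0]),
                np.exp(rng.normal(0.8, 0.5) + 0.02 * np.array([0.0, 10.0, 20.0])),
            )
            for i in range(3)
        }
        cohort = make_cohort(series)
        spec = mg.RandomEffectSpec(("log_v0",))
        theta = np.array([0.8, 0.02])
        psi = np.array([[0.25]])
        s2 = 0.04
        ll_q = marginal_loglik_quadrature(
            "exponential", spec, cohort, theta, psi, s2, n_nodes=41
        )
        draws = rng.normal(0.0, 0.5, size=200_000)
        total, total_se = 0.0, 0.0
        for patient in cohort:
            t, y = patient.times, np.log(patient.volumes)
            mu = theta[0] + draws[:, None] + theta[1] * t[None, :]
            logp = np.sum(norm.logpdf(y[None, :], mu, math.sqrt(s2)), axis=1)
            m = logp.max()
            w = np.exp(logp - m)
            total += m + math.log(w.mean())
            total_se += w.std() / (w.mean() * math.sqrt(w.size))
        assert abs(ll_q - total) < 3 * max(total_se, 1e-4)


class TestInformationCriteria:
    def test_identities(self):
        aic, bic = mg.information_criteria(-100.0, 5, 200)
        assert aic == 2 * 5 + 200.0
        assert bic == pytest.approx(5 * math.log(200) + 200.0)
        assert mg.information_criteria(0.0, 0, 1) == (0.0, 0.0)

    def test_rounded_published_pair_consistency(self):
        # arithmetic from a rounded log-likelihood lands within rounding slack
        aic, _ = mg.information_criteria(-525.8, 11, 1394)
        assert aic == pytest.approx(1073.6, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mg.information_criteria(0.0, -1, 10)
        with pytest.raises(ValueError):
            mg.information_criteria(0.0, 1, 0)


class TestFit:
    def test_recovers_truth_without_noise(self):
        cohort, _ = simulate_cohort(
            SimulationConfig(n_patients=8, seed=5, sigma=0.0,
                             re_sd=(0.0, 0.0), re_corr=0.0)
        )
        fit = mg.fit_nlme(
            "gompertz", None, cohort,
            config=mg.FitConfig(n_starts=1, compute_se=False),
        )
        assert fit.theta_hat["log_v0"] == pytest.approx(math.log(2.6), abs=5e-3)
        assert fit.theta_hat["log_k"] == pytest.approx(math.log(2.6) + 1.0, abs=2e-2)
        assert fit.theta_hat["alpha"] == pytest.approx(0.02, rel=2e-2)
        assert fit.sigma2_hat < 1e-4

    def test_matches_statsmodels_linear_mixed_model(self, rng):
        """Independent LMM oracle: same ML estimates, SEs and log-likelihood."""
        sm = pytest.importorskip("statsmodels.api")
        series, rows = {}, []
        for i in range(30):
            a = 5 + rng.normal(0, 1.5)
            t = np.sort(np.concatenate([[0.0], rng.uniform(1, 40, 4)]))
            y = np.maximum(a + 0.3 * t + rng.normal(0, 0.8, 5), 0.05)
            series[f"P{i:02d}"] = (t, y)
            rows += [{"pid": f"P{i:02d}", "t": tt, "y": vv} for tt, vv in zip(t, y)]
        cohort = make_cohort(series)
        fit = mg.fit_nlme(
            "linear", mg.RandomEffectSpec(("intercept",)), cohort,
            config=mg.FitConfig(n_starts=2),
        )
        oracle = sm.MixedLM.from_formula(
            "y ~ t", groups="pid", data=pd.DataFrame(rows)
        ).fit(reml=False)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        assert fit.theta_hat["intercept"] == pytest.approx(
            oracle.params["Intercept"], abs=1e-4
        )
        assert fit.theta_hat["slope"] == pytest.approx(oracle.params["t"], abs=1e-5)
        assert fit.se_theta["intercept"] == pytest.approx(
            oracle.bse["Intercept"], rel=1e-3
        )
        assert fit.se_theta["slope"] == pytest.approx(oracle.bse["t"], rel=1e-3)

    def test_fit_result_invariants(self, gompertz_cohort_10):
        fit = mg.fit_nlme(
            "gompertz", None, gompertz_cohort_10,
            config=mg.FitConfig(n_starts=1, compute_se=False),
        )
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(
            fit.k * math.log(fit.n_obs) - 2 * fit.loglik
        )
        eigs = np.linalg.eigvalsh(fit.psi_hat)
        assert np.all(eigs > -1e-10)
        assert fit.n_obs == gompertz_cohort_10.n_scans

    def test_covariate_design_validation(self, gompertz_cohort_10):
        bad = CovariateDesign(("x",), np.ones((3, 1)), "log_k")
        with pytest.raises(ValueError, match="rows must match"):
            mg.fit_nlme("gompertz", None, gompertz_cohort_10, covariate_design=bad)


class TestCompare:
    def test_identical_models_tie_stably(self, gompertz_cohort_10):
        table = mg.compare_models(
            gompertz_cohort_10, models=("gompertz", "gompertz"),
            config=mg.FitConfig(n_starts=1, compute_se=False),
        )
        assert len(table) == 2
        assert table.loc[0, "loglik"] == table.loc[1, "loglik"]
        assert list(table["rank"]) == [1, 2]

    def test_jacobian_correction_moves_log_scale_models_only(
        self, gompertz_cohort_10
    ):
        table = mg.compare_models(
            gompertz_cohort_10, models=("linear", "gompertz"),
            config=mg.FitConfig(n_starts=1, compute_se=False),
            jacobian_correction=True,
        )
        by_model = table.set_index("model")
        sum_log_v = sum(
            float(np.sum(np.log(p.volumes))) for p in gompertz_cohort_10
        )
        assert by_model.loc["linear", "loglik_volume_scale"] == pytest.approx(
            by_model.loc["linear", "loglik"]
        )
        assert by_model.loc["gompertz", "loglik_volume_scale"] == pytest.approx(
            by_model.loc["gompertz", "loglik"] - sum_log_v
        )

    def test_requires_two_models(self, gompertz_cohort_10):
        with pytest.raises(ValueError):
            mg.compare_models(gompertz_cohort_10, models=("gompertz",))
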