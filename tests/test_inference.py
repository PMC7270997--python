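"""Maximum-likelihood fitting, standard errors, and the sklearn estimator."""

import numpy as np
import pytest

from nexdist import (
    ModelSpec,
    ParametricDensityMLE,
    fit_mle,
    log_likelihood,
    new_weibull,
    standard_errors,
)
from nexdist.competitors import REGISTRY


class TestLogLikelihood:
    def test_hand_value_single_point(self):
        # NE-W(theta=1, a=1, gamma=1) at x = ln 2: g = 2fF = 0.5
        ll = log_likelihood("new", (1.0, 1.0, 1.0), [np.log(2.0)])
        assert ll == pytest.approx(np.log(0.5), rel=1e-12)

    def test_iid_additivity(self, rng):
        x1 = new_weibull(1.5, 1.2, 0.8).rvs(40, seed=rng)
        x2 = new_weibull(1.5, 1.2, 0.8).rvs(60, seed=rng)
        p = (1.2, 0.8, 1.5)
        assert log_likelihood("new", p, np.concatenate([x1, x2])) == pytest.approx(
            log_likelihood("new", p, x1) + log_likelihood("new", p, x2), rel=1e-12
        )

    def test_equals_sum_of_log_density(self, rng):
        x = new_weibull(2.0, 1.0, 1.0).rvs(50, seed=rng)
        m = new_weibull(2.0, 1.0, 1.0)
        assert log_likelihood("new", (1.0, 1.0, 2.0), x) == pytest.approx(
            float(np.sum(m.logpdf(x))), abs=1e-10
        )

    def test_domain_error_names_offending_index(self):
        with pytest.raises(ValueError, match="index 2"):
            log_likelihood("new", (1.0, 1.0, 1.0), [1.0, 2.0, -1.0])


class TestFitMle:
    def test_parameter_recovery_large_sample(self):
        # generating parameters (alpha=0.9, theta=1.2, gamma=0.7)
        truth = np.array([0.9, 0.7, 1.2])
        x = new_weibull(1.2, 0.9, 0.7).rvs(5000, seed=101)
        fit = fit_mle("new", x, n_restarts=2, seed=0)
        assert fit.converged
        se = np.array([fit.standard_errors[k] for k in fit.param_order])
        err = np.abs(fit.theta_hat - truth)
        assert np.all(err < 3 * se)

    def test_optimum_beats_truth(self):
        x = new_weibull(1.2, 0.9, 0.7).rvs(400, seed=5)
        fit = fit_mle("new", x, n_restarts=1, seed=0)
        assert fit.loglik >= log_likelihood("new", (0.9, 0.7, 1.2), x) - 1e-6

    def test_improves_on_any_explicit_start(self):
        x = new_weibull(1.2, 0.9, 0.7).rvs(200, seed=9)
        init = (2.0, 2.0, 2.0)
        fit = fit_mle("new", x, init=init, n_restarts=0)
        assert fit.loglik >= log_likelihood("new", init, x)

    def test_rejects_nonpositive_data(self):
        with pytest.raises(ValueError):
            fit_mle("new", [1.0, -1.0, 2.0])

    def test_rejects_empty_data(self):
        with pytest.raises(ValueError):
            fit_mle("new", [])

    def test_invariant_to_data_ordering_and_rerun(self, rng):
        x = new_weibull(1.2, 0.9, 0.7).rvs(300, seed=rng)
        f1 = fit_mle("new", x, n_restarts=1, seed=7)
        f2 = fit_mle("new", x[::-1].copy(), n_restarts=1, seed=7)
        f3 = fit_mle("new", x, n_restarts=1, seed=7)
        for k in f1.param_order:
            assert f1.estimates[k] == pytest.approx(f2.estimates[k], rel=1e-6)
            assert f1.estimates[k] == f3.estimates[k]


EXPON = ModelSpec(
    name="_expon",
    param_names=("gamma",),
    cdf=lambda p, x: -np.expm1(-p[0] * np.maximum(np.asarray(x, float), 0.0)),
    logpdf=lambda p, x: np.where(
        np.asarray(x, float) > 0, np.log(p[0]) - p[0] * np.asarray(x, float), -np.inf
    ),
    init=lambda d: np.array([1.0 / np.mean(d)]),
)


@pytest.fixture
def expon_registered():
    REGISTRY["_expon"] = EXPON
    yield EXPON
    del REGISTRY["_expon"]


class TestStandardErrors:
    def test_exponential_analytic_fisher_information(self, expon_registered):
        # one-parameter exponential: SE(gamma-hat) = gamma-hat / sqrt(n)
        x = np.random.default_rng(3).exponential(scale=2.0, size=400)
        fit = fit_mle("_expon", x, n_restarts=0)
        g = fit.estimates["gamma"]
        assert g == pytest.approx(1.0 / np.mean(x), rel=1e-5)
        assert fit.standard_errors["gamma"] == pytest.approx(
            g / np.sqrt(x.size), rel=1e-3
        )

    def test_all_positive_when_information_definite(self):
        x = new_weibull(1.2, 0.9, 0.7).rvs(800, seed=17)
        fit = fit_mle("new", x, n_restarts=1, seed=0)
        se = np.array([fit.standard_errors[k] for k in fit.param_order])
        assert np.all(np.isnan(se) | (se > 0))

    def test_se_shrinks_like_sqrt_n(self, expon_registered):
        # doubling n shrinks the SE by about sqrt(2), averaged over replicates
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(10):
            xs = rng.exponential(scale=1.5, size=800)
            f_small = fit_mle("_expon", xs[:400], n_restarts=0)
            f_big = fit_mle("_expon", xs, n_restarts=0)
            ratios.append(
                f_small.standard_errors["gamma"] / f_big.standard_errors["gamma"]
            )
        assert np.mean(ratios) == pytest.approx(np.sqrt(2.0), rel=0.1)

    def test_requires_converged_fit(self):
        from nexdist.inference import FitResult

        bad = FitResult(
            model_name="new",
            estimates={},
            standard_errors={},
            loglik=np.nan,
            n=0,
            converged=False,
            n_restarts_used=0,
        )
        with pytest.raises(ValueError):
            standard_errors(bad, [1.0])


class TestSklearnEstimator:
    def test_get_set_params_round_trip(self):
        est = ParametricDensityMLE(model="weibull", n_restarts=5)
        params = est.get_params()
        assert params["model"] == "weibull" and params["n_restarts"] == 5
        est.set_params(n_restarts=2)
        assert est.n_restarts == 2

    def test_fitted_attributes_and_score(self, rng):
        x = new_weibull(1.5, 1.2, 0.8).rvs(300, seed=rng)
        est = ParametricDensityMLE(model="new", n_restarts=1, random_state=0).fit(x)
        assert est.converged_
        assert set(est.params_) == {"alpha", "gamma", "theta"}
        assert est.score(x) == pytest.approx(est.loglik_, rel=1e-12)
        assert np.all(np.isfinite(est.score_samples(x)))

    def test_accepts_column_vector(self, rng):
        x = new_weibull(1.5, 1.2, 0.8).rvs(100, seed=rng)
        est = ParametricDensityMLE(model="weibull", n_restarts=0).fit(x[:, None])
        assert est.converged_

    def test_sample_matches_fitted_cdf(self, rng):
        from scipy import stats

        x = new_weibull(2.0, 1.5, 1.0).rvs(400, seed=rng)
        est = ParametricDensityMLE(model="new", n_restarts=1, random_state=0).fit(x)
        draws = est.sample(2000, random_state=1)
        assert stats.kstest(draws, est.cdf).pvalue > 0.01

    def test_works_in_sklearn_model_selection(self, rng):
        from sklearn.model_selection import KFold, cross_val_score

        x = new_weibull(1.5, 1.2, 0.8).rvs(200, seed=rng)[:, None]
        scores = cross_val_score(
            ParametricDensityMLE(model="weibull", n_restarts=0),
            x,
            cv=KFold(n_splits=3),
        )
        assert np.all(np.isfinite(scores))
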