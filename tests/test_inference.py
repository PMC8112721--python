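import numpy as np
import pytest

from tsg.inference import (
    SineWeibull,
    TransformedSinWeibull,
    fit_mle,
    loglik,
    score,
    standard_errors,
)
from tsg.tsw import TSWParams, tsw_logpdf, tsw_rvs

HALF_PI = np.pi / 2.0


class TestLogLikelihood:
    def test_single_observation_equals_logpdf(self):
        params = (0.4, 1.2, 2.1)
        x = np.array([0.7])
        assert loglik(x, *params) == pytest.approx(float(tsw_logpdf(params, 0.7)), abs=1e-12)

    def test_zero_density_gives_minus_inf_not_exception(self):
        assert loglik(np.array([-1.0, 2.0]), 0.4, 1.0, 2.0) == -np.inf
        assert loglik(np.array([1.0, 2.0]), 0.4, -1.0, 2.0) == -np.inf

    def test_sw_model_rejects_nonzero_lam(self):
        with pytest.raises(ValueError):
            loglik(np.array([1.0]), 0.3, 1.0, 1.0, model="sw")


class TestScore:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        data = tsw_rvs((0.4, 1.0, 2.0), 40, seed=9)
        h = 1e-6
        for _ in range(20):
            lam = rng.uniform(0.05, 0.95)
            alpha = rng.uniform(0.3, 3.0)
            beta = rng.uniform(0.8, 4.0)
            g = score(data, lam, alpha, beta)
            fd = np.array(
                [
                    (loglik(data, lam + h, alpha, beta) - loglik(data, lam - h, alpha, beta)),
                    (loglik(data, lam, alpha + h, beta) - loglik(data, lam, alpha - h, beta)),
                    (loglik(data, lam, alpha, beta + h) - loglik(data, lam, alpha, beta - h)),
                ]
            ) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-4)

    def test_lam_zero_component_reduction(self):
        # at lam=0 the lam-score is sum [(pi/2) G sin((pi/2)G) - cos((pi/2)G)] / cos((pi/2)G)
        data = tsw_rvs((0.0, 1.0, 2.0), 30, seed=4)
        alpha, beta = 1.1, 1.9
        G = 1.0 - np.exp(-alpha * data**beta)
        expected = np.sum(
            (HALF_PI * G * np.sin(HALF_PI * G) - np.cos(HALF_PI * G)) / np.cos(HALF_PI * G)
        )
        assert score(data, 0.0, alpha, beta)[0] == pytest.approx(expected, rel=1e-12)

    def test_small_gradient_at_interior_optimum(self, tsw_fit_tensile):
        lam, alpha, beta = tsw_fit_tensile.params.astuple()
        g = score(tsw_fit_tensile.data, lam, alpha, beta)
        # scaled (working-coordinate) gradient at the optimum
        scaled = np.array([g[0], g[1] * alpha, g[2] * beta])
        assert np.max(np.abs(scaled)) < 1e-4


class TestFit:
    def test_recovers_truth_within_three_se(self):
        truth = TSWParams(0.3, 3.0, 5.0)
        data = tsw_rvs(truth, 5000, seed=12)
        res = fit_mle(data, model="tsw", seed=0)
        assert res.converged
        for est, se, true in zip(res.fitted_params, res.bse, truth.astuple()):
            assert abs(est - true) < 3 * se

    def test_nested_loglik_ordering(self, tsw_fit_tensile, sw_fit_tensile,
                                    tsw_fit_breaking, sw_fit_breaking):
        assert tsw_fit_tensile.llf >= sw_fit_tensile.llf
        assert tsw_fit_breaking.llf >= sw_fit_breaking.llf

    def test_results_loglik_consistent(self, tsw_fit_tensile):
        r = tsw_fit_tensile
        assert r.llf == loglik(r.data, *r.params.astuple())

    def test_rejects_degenerate_data(self):
        with pytest.raises(ValueError):
            fit_mle(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            fit_mle(np.array([1.0, -2.0, 3.0, 4.0, 5.0]))

    def test_model_name_validation(self):
        with pytest.raises(ValueError):
            fit_mle(np.linspace(1, 2, 10), model="weibull")

    def test_model_object_interface(self, tensile):
        model = TransformedSinWeibull(tensile)
        res = model.fit(seed=0)
        assert res.model == "tsw"
        assert model.loglike(res.params) == pytest.approx(res.llf)
        summary = res.summary()
        assert "lam" in summary and "std err" in summary
        rep = res.to_report()
        assert rep["format"] == "tsg-report/1"
        assert set(rep["estimates"]) == {"lam", "alpha", "beta"}

    def test_sw_model_object(self, tensile):
        res = SineWeibull(tensile).fit(seed=0)
        assert res.model == "sw"
        assert res.params.lam == 0.0
        assert res.k_params == 2


class TestStandardErrors:
    def test_step_robustness(self, tsw_fit_tensile):
        base = np.array(tsw_fit_tensile.bse)
        halved = standard_errors(tsw_fit_tensile, rel_step=5e-5)
        np.testing.assert_allclose(halved, base, rtol=1e-4)
        standard_errors(tsw_fit_tensile)  # restore default-step values

    def test_conf_int_truncated_to_unit_interval(self, tsw_fit_tensile):
        ci = tsw_fit_tensile.conf_int()
        assert 0.0 <= ci[0, 0] <= ci[0, 1] <= 1.0

    def test_observed_info_positive_definite_at_mle(self, tsw_fit_tensile):
        assert tsw_fit_tensile.se_flag is None
        eigvals = np.linalg.eigvalsh(tsw_fit_tensile.observed_info)
        assert np.all(eigvals > 0)


class TestRecoveryStudy:
    def test_median_error_below_asymptotic_se(self):
        # 200 refits at n=200 from the S1 truth
        truth = TSWParams(0.3, 3.0, 5.0)
        errs, ses = [], []
        for rep in range(200):
            data = tsw_rvs(truth, 200, seed=np.random.SeedSequence(100, spawn_key=(rep,)))
            try:
                res = fit_mle(data, model="tsw", starts=3, seed=rep)
            except Exception:
                continue
            errs.append(np.abs(res.fitted_params - np.array(truth.astuple())))
            ses.append(res.bse)
        errs = np.array(errs)
        ses = np.asarray(ses, dtype=float)
        med_err = np.median(errs, axis=0)
        med_se = np.nanmedian(ses, axis=0)
        assert np.all(med_err < med_se)
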