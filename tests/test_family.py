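import numpy as np
import pytest
from scipy import integrate

from tsg.family import (
    TSG,
    f_star_cdf,
    hrf_critical_points,
    likelihood_ratio,
    make_baseline,
    mixture_check,
    ordering_gap,
    pdf_critical_points,
    register_baseline,
    reliability,
    series_coefficients,
    tail_coefficients,
)
from tsg.transform import t_lambda
from tsg.tsw import as_tsg

HALF_PI = np.pi / 2.0


def random_configs(n, seed=0):
    """Random (lam, baseline) pairs over the registered baselines."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        lam = rng.uniform()
        kind = rng.choice(["uniform", "exponential", "weibull"])
        if kind == "uniform":
            b = make_baseline("uniform", 0.0, rng.uniform(0.5, 3.0))
        elif kind == "exponential":
            b = make_baseline("exponential", rng.uniform(0.3, 3.0))
        else:
            b = make_baseline("weibull", rng.uniform(0.3, 3.0), rng.uniform(0.5, 4.0))
        out.append(TSG(lam, b))
    return out


class TestCdfPdf:
    def test_uniform_baseline_examples(self, unit_uniform):
        assert TSG(0.3, unit_uniform).cdf(1.0) == 1.0
        assert TSG(0.0, unit_uniform).cdf(0.5) == pytest.approx(np.sin(np.pi / 4), abs=1e-15)
        expected = np.sin(np.pi / 4) - (np.pi / 4) * np.cos(np.pi / 4)
        assert TSG(1.0, unit_uniform).cdf(0.5) == pytest.approx(expected, abs=1e-15)

    def test_pdf_boundary_values(self, unit_uniform):
        assert TSG(0.0, unit_uniform).pdf(0.0) == pytest.approx(HALF_PI, abs=1e-14)
        assert TSG(1.0, unit_uniform).pdf(0.0) == pytest.approx(0.0, abs=1e-14)

    def test_pdf_normalises_over_random_configurations(self):
        for dist in random_configs(20, seed=11):
            lo, hi = dist.baseline.support
            total, _ = integrate.quad(
                lambda x: float(np.asarray(dist.pdf(x))), lo, hi, limit=200
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_cdf_pdf_consistency_by_finite_differences(self):
        for dist in random_configs(6, seed=3):
            lo, hi = dist.baseline.support
            hi = min(hi, float(np.asarray(dist.quantile(0.999))))
            x = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), 50)
            h = 1e-6 * (hi - lo)
            fd = (np.asarray(dist.cdf(x + h)) - np.asarray(dist.cdf(x - h))) / (2 * h)
            np.testing.assert_allclose(fd, np.asarray(dist.pdf(x)), atol=1e-6 / (hi - lo))

    def test_lam_zero_reduces_to_sine_family(self, unit_uniform):
        x = np.linspace(0, 1, 101)
        dist = TSG(0.0, unit_uniform)
        np.testing.assert_allclose(dist.cdf(x), np.sin(HALF_PI * x), atol=1e-15)


class TestSurvivalHazard:
    def test_sf_complements_cdf(self, unit_uniform):
        dist = TSG(0.42, unit_uniform)
        x = np.linspace(0, 1, 51)
        np.testing.assert_allclose(
            np.asarray(dist.sf(x)) + np.asarray(dist.cdf(x)), 1.0, atol=1e-15
        )

    def test_hrf_times_sf_is_pdf(self, unit_uniform):
        dist = TSG(0.42, unit_uniform)
        x = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(
            np.asarray(dist.hrf(x)) * np.asarray(dist.sf(x)),
            np.asarray(dist.pdf(x)),
            rtol=1e-12,
        )

    def test_hrf_upper_tail_matches_baseline_hazard(self, unit_uniform):
        # near the upper end the hazard is equivalent to g/(1-G) (any lam > 0)
        dist = TSG(0.5, unit_uniform)
        x = 1.0 - 1e-5
        baseline_h = 1.0 / (1.0 - x)
        assert dist.hrf(x) == pytest.approx(baseline_h, rel=1e-3)

    def test_hrf_warns_and_returns_inf_when_sf_underflows(self, unit_uniform):
        dist = TSG(0.3, unit_uniform)
        with pytest.warns(RuntimeWarning):
            assert dist.hrf(1.0) == np.inf


class TestQuantileSampling:
    def test_quantile_endpoints(self, unit_uniform):
        dist = TSG(0.6, unit_uniform)
        assert dist.quantile(0.0) == 0.0
        assert dist.quantile(1.0) == 1.0

    def test_quantile_round_trip(self, unit_uniform):
        dist = TSG(0.6, unit_uniform)
        x = 0.37
        assert dist.quantile(dist.cdf(x), tol=1e-13) == pytest.approx(x, abs=1e-9)

    def test_rvs_reproducible_and_converges_to_cdf(self, unit_uniform):
        dist = TSG(0.3, unit_uniform)
        s1 = dist.rvs(1000, seed=42)
        s2 = dist.rvs(1000, seed=42)
        np.testing.assert_array_equal(s1, s2)
        big = dist.rvs(5000, seed=1)
        u = np.sort(np.asarray(dist.cdf(np.sort(big))))
        i = np.arange(1, big.size + 1)
        d = max(np.max(i / big.size - u), np.max(u - (i - 1) / big.size))
        assert d < 0.03  # 95% Kolmogorov band ~ 1.36/sqrt(n)

    def test_rvs_validation(self, unit_uniform):
        with pytest.raises(ValueError):
            TSG(0.3, unit_uniform).rvs(0, seed=1)


class TestFamilyIdentities:
    def test_mixture_identity(self, unit_uniform):
        dist = TSG(0.37, unit_uniform)
        x = np.linspace(0, 1, 200)
        np.testing.assert_allclose(mixture_check(dist, x), dist.cdf(x), atol=1e-12)

    def test_stochastic_ordering_over_random_pairs(self, unit_uniform):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 100)
        for _ in range(50):
            l1, l2 = np.sort(rng.uniform(size=2))
            assert np.all(ordering_gap(x, l1, l2, unit_uniform) >= -1e-14)

    def test_lower_bound_cdf_for_small_lam(self, unit_uniform):
        x = np.linspace(0, 1, 200)
        for lam in (0.0, 0.3, 0.6):  # all <= 2/pi ~ 0.6366
            gap = np.asarray(TSG(lam, unit_uniform).cdf(x)) - f_star_cdf(x, unit_uniform)
            assert np.all(gap >= -1e-14)

    def test_likelihood_ratio_monotone(self, unit_uniform):
        x = np.linspace(0.01, 0.99, 300)
        r = likelihood_ratio(x, 0.2, 0.8, unit_uniform)
        assert np.all(np.diff(r) <= 1e-12)
        np.testing.assert_allclose(likelihood_ratio(x, 0.5, 0.5, unit_uniform), 1.0, atol=1e-15)

    def test_tail_coefficients(self):
        assert tail_coefficients(0.0) == (HALF_PI, 0.0)
        lower, upper = tail_coefficients(1.0)
        assert lower == 0.0 and upper == pytest.approx(np.pi**2 / 4)
        # ratio limit at the lower tail: F/G -> (pi/2)(1-lam)
        lam = 0.5
        G = 1e-6
        assert t_lambda(G, lam) / G == pytest.approx(HALF_PI * (1 - lam), rel=1e-5)


class TestCriticalPoints:
    def test_unimodal_tsw_pdf(self):
        dist = as_tsg((0.5, 1.0, 3.0))
        pts = pdf_critical_points(dist, bracket=(1e-3, 3.0))
        assert len(pts) == 1
        x_star, kind = pts[0]
        assert kind == "max"
        # brute-force grid oracle
        grid = np.linspace(1e-3, 3.0, 20000)
        assert abs(grid[np.argmax(dist.pdf(grid))] - x_star) < 1e-3

    def test_root_residual_small(self):
        dist = as_tsg((0.5, 1.0, 3.0))
        (x_star, _), = pdf_critical_points(dist, bracket=(1e-3, 3.0))
        h = 1e-6 * (3.0 - 1e-3)
        res = (np.log(dist.pdf(x_star + h)) - np.log(dist.pdf(x_star - h))) / (2 * h)
        assert abs(res) < 1e-8

    def test_hrf_with_interior_extrema(self):
        # beta < 1 with large lam: hazard falls from +inf, turns, and falls
        # again - two interior critical points (grid oracle agrees)
        dist = as_tsg((0.9, 1.0, 0.6))
        pts = hrf_critical_points(dist, bracket=(0.01, 4.0))
        assert len(pts) >= 1
        grid = np.linspace(0.01, 4.0, 20000)
        h = np.asarray(dist.hrf(grid))
        changes = np.sum(np.abs(np.diff(np.sign(np.diff(np.log(h))))) > 0)
        assert changes == len(pts)

    def test_monotone_hrf_yields_empty_list(self):
        dist = as_tsg((0.7, 1.0, 3.0))
        assert hrf_critical_points(dist, bracket=(0.05, 3.0)) == []


class TestSeriesExpansion:
    def test_leading_coefficient(self):
        for lam in (0.0, 0.33, 1.0):
            c = series_coefficients(lam, K=5)
            assert c.a[0] == pytest.approx(HALF_PI * (1 - lam), abs=1e-15)

    def test_coefficients_sum_to_one(self):
        for lam in (0.0, 0.4, 1.0):
            assert np.sum(series_coefficients(lam, K=30).a) == pytest.approx(1.0, abs=1e-12)

    def test_truncated_series_matches_cdf(self, unit_uniform):
        c = series_coefficients(0.62, K=30)
        G = np.linspace(0.0, 0.999, 400)
        np.testing.assert_allclose(
            c.cdf_series(G), t_lambda(G, 0.62), rtol=0, atol=1e-10
        )

    def test_tail_bound_is_tiny_at_default_truncation(self):
        assert series_coefficients(0.5, K=30).tail_bound < 1e-30


class TestReliability:
    def test_identical_distributions(self):
        assert reliability(0.5, 0.5) == 0.5

    def test_extreme_pair(self):
        assert reliability(1.0, 0.0) == pytest.approx(0.5 + (np.pi**2 - 4) / 16, abs=1e-15)
        assert reliability(1.0, 0.0) == pytest.approx(0.866850, abs=1e-6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            l1, l2 = rng.uniform(size=2)
            assert reliability(l1, l2) + reliability(l2, l1) == pytest.approx(1.0, abs=1e-15)

    def test_closed_form_agrees_with_quadrature(self):
        # R = integral of F(x; lam2) f(x; lam1) dx, reduced to the unit interval
        rng = np.random.default_rng(21)
        for _ in range(20):
            l1, l2 = rng.uniform(size=2)

            def integrand(u):
                F2 = np.sin(HALF_PI * u) - l2 * HALF_PI * u * np.cos(HALF_PI * u)
                f1 = HALF_PI * (
                    l1 * HALF_PI * u * np.sin(HALF_PI * u) + (1 - l1) * np.cos(HALF_PI * u)
                )
                return F2 * f1

            numeric, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12)
            assert reliability(l1, l2) == pytest.approx(numeric, abs=1e-8)


class TestBaselineRegistry:
    def test_unknown_baseline(self):
        with pytest.raises(ValueError):
            make_baseline("cauchy")

    def test_pluggable_baseline(self, unit_uniform):
        register_baseline("unit_uniform_alias", lambda: unit_uniform)
        b = make_baseline("unit_uniform_alias")
        assert b.cdf(0.25) == pytest.approx(0.25)

    def test_quantile_cdf_spot_check(self):
        b = make_baseline("weibull", 2.0, 1.5)
        x = np.array([0.2, 0.7, 1.3])
        np.testing.assert_allclose(b.ppf(b.cdf(x)), x, rtol=1e-12)
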