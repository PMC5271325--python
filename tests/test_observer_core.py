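"""Observer core: mapping, posteriors, decision rules, response marginal."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import comreach as cr
from comreach import _engine
from conftest import random_com_mixture


def com_oracle(rho, dim_d, half=12.0):
    """Brute-force mass-weighted balance point: masses ~ r**D at +-half."""
    r1, r2 = 1.0, math.exp(rho)
    m1, m2 = r1**dim_d, r2**dim_d
    return (m2 * half + m1 * (-half)) / (m1 + m2)


class TestComMap:
    @pytest.mark.parametrize(
        "rho,dim_d,expected",
        [
            (0.0, 2.0, 0.0),
            (math.log(1.5), 2.0, 12 * (1.5**2 - 1) / (1.5**2 + 1)),  # 4.6154
            (math.log(1.5), 3.0, 12 * (1.5**3 - 1) / (1.5**3 + 1)),  # 6.5143
        ],
    )
    def test_matches_mass_weighted_average(self, rho, dim_d, expected):
        assert cr.com_map(rho, dim_d) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_oracle_on_random_inputs(self, rng):
        rho = rng.uniform(-2, 2, 100)
        dim_d = rng.uniform(0.2, 5, 100)
        for r, d in zip(rho, dim_d):
            assert cr.com_map(r, d) == pytest.approx(com_oracle(r, d), abs=1e-10)

    def test_odd_increasing_bounded(self, rng, geometry):
        rho = np.sort(rng.uniform(-4, 4, 200))
        s = cr.com_map(rho, 1.7, geometry)
        np.testing.assert_allclose(s, -cr.com_map(-rho, 1.7, geometry), atol=1e-12)
        assert (np.diff(s) > 0).all()
        assert (np.abs(s) < geometry.half_length).all()

    def test_rejects_nonpositive_exponent(self):
        with pytest.raises(ValueError):
            cr.com_map(0.1, 0.0)


class TestPosteriorRho:
    def test_single_component_conjugate_update(self):
        mu0, sd0, sr, rho_m = 0.3, 0.2, 0.1, 0.55
        prior = cr.GaussianMixture1D([1.0], [mu0], [sd0])
        post = cr.posterior_rho(rho_m, prior, sr)
        expect_mean = (sr**2 * mu0 + sd0**2 * rho_m) / (sd0**2 + sr**2)
        expect_var = sd0**2 * sr**2 / (sd0**2 + sr**2)
        assert post.means[0] == pytest.approx(expect_mean, abs=1e-12)
        assert post.sds[0] == pytest.approx(math.sqrt(expect_var), abs=1e-12)
        assert post.weights[0] == 1.0

    def test_central_delta_dominates_at_zero_measurement(self, prior):
        # Oracle: w0 = (1/3) N(0|0, sr^2) / [(1/3) N(0|0,sr^2)
        #   + 2 (1/3) N(0|log1.5, sr^2 + 0.1^2)], evaluated directly = 0.99704.
        post = cr.posterior_rho(0.0, prior, 0.063)
        assert post.weights[1] == pytest.approx(0.99704, abs=5e-5)
        assert post.sds[1] == 0.0 and post.means[1] == 0.0

    def test_weights_match_numerical_integration(self, prior, rng):
        # Marginal evidence per component by direct quadrature of
        # measurement likelihood x prior component.
        for rho_m in (0.0, 0.405, -0.2, 0.7):
            sr = 0.063
            post = cr.posterior_rho(rho_m, prior, sr)
            ev = []
            for w, mu, sd in zip(prior.weights, prior.means, prior.sds):
                if sd == 0:
                    ev.append(w * stats.norm.pdf(rho_m, mu, sr))
                else:
                    f = lambda x: stats.norm.pdf(rho_m, x, sr) * stats.norm.pdf(x, mu, sd)
                    val, _ = integrate.quad(f, mu - 8 * sd, mu + 8 * sd, epsabs=1e-13)
                    ev.append(w * val)
            ev = np.array(ev) / sum(ev)
            np.testing.assert_allclose(post.weights, ev, atol=1e-8)

    def test_side_component_precision_weighting(self, prior):
        post = cr.posterior_rho(0.405, prior, 0.063)
        assert post.weights[2] > 0.99
        lo, hi = sorted((0.405, math.log(1.5)))
        assert lo <= post.means[2] <= hi


class TestPosteriorCom:
    def test_delta_maps_exactly(self, prior):
        post = cr.posterior_rho(0.0, prior, 0.05)
        pc = cr.posterior_com(post, 2.0)
        assert pc.means[1] == 0.0 and pc.sds[1] == 0.0
        np.testing.assert_allclose(pc.weights, post.weights)

    def test_moments_match_high_resolution_quadrature(self):
        mu, sd, d = math.log(1.5), 0.0535, 2.0
        mix = cr.GaussianMixture1D([1.0], [mu], [sd])
        pc = cr.posterior_com(mix, d)
        xs = np.linspace(mu - 10 * sd, mu + 10 * sd, 40001)
        pdf = stats.norm.pdf(xs, mu, sd)
        fs = cr.com_map(xs, d)
        m_ref = np.trapezoid(pdf * fs, xs)
        v_ref = np.trapezoid(pdf * (fs - m_ref) ** 2, xs)
        assert pc.means[0] == pytest.approx(m_ref, abs=1e-6)
        assert pc.sds[0] == pytest.approx(math.sqrt(v_ref), rel=1e-6)
        # linearization sanity: sd close to |f'(mu)| sd within 5%
        fprime = 12.0 * d / 2 / math.cosh(d * mu / 2) ** 2
        assert pc.sds[0] == pytest.approx(abs(fprime) * sd, rel=0.05)

    def test_narrow_component_limit_is_pointwise_map(self):
        mu = 0.3
        for sd in (1e-3, 1e-5):
            mix = cr.GaussianMixture1D([1.0], [mu], [sd])
            pc = cr.posterior_com(mix, 2.4)
            assert pc.means[0] == pytest.approx(cr.com_map(mu, 2.4), abs=1e-4)


def grid_oracle_pre(mix, sigma_err, step=0.001, half=12.0):
    grid = np.arange(-half, half + step / 2, step)
    v = mix.sds**2 + sigma_err**2
    g = (mix.weights * sigma_err / np.sqrt(v) *
         np.exp(-0.5 * (grid[:, None] - mix.means) ** 2 / v)).sum(axis=1)
    return grid[np.argmax(g)]


def grid_oracle_adj(mix, r0, params, step=0.001, half=12.0):
    grid = np.arange(-half, half + step / 2, step)
    v = mix.sds**2 + params.sigma_err**2
    g = (mix.weights * params.sigma_err / np.sqrt(v) *
         np.exp(-0.5 * (grid[:, None] - mix.means) ** 2 / v)).sum(axis=1)
    g = g + params.alpha * np.exp(-0.5 * ((grid - r0) * params.inv_sigma_adj) ** 2)
    return grid[np.argmax(g)]


class TestEndpoints:
    def test_single_component_optimum_is_mean(self):
        mix = cr.GaussianMixture1D([1.0], [3.2], [0.7], space="com")
        assert cr.preliminary_endpoint(mix) == pytest.approx(3.2, abs=1e-6)

    def test_two_bump_global_optimum_matches_dense_grid(self):
        for sep, sd in [(4.6, 0.8), (1.0, 0.8), (4.6, 3.0)]:
            mix = cr.GaussianMixture1D(
                [0.5, 0.5], [-sep, sep], [sd, sd], space="com"
            )
            got = cr.preliminary_endpoint(mix)
            ref = grid_oracle_pre(mix, cr.SCORE_SIGMA)
            assert abs(abs(got) - abs(ref)) < 2e-3  # symmetric pair: compare |s|

    def test_paper_prior_zero_measurement_prefers_center(self, prior):
        pc = cr.posterior_com(cr.posterior_rho(0.0, prior, 0.063), 2.0)
        assert cr.preliminary_endpoint(pc) == pytest.approx(0.0, abs=1e-6)

    def test_flat_objective_flagged_with_midpoint(self):
        mix = cr.GaussianMixture1D([1.0], [0.0], [1e6], space="com")
        s, flat = cr.preliminary_endpoint(mix, full_output=True)
        assert flat and s == pytest.approx(0.0, abs=1e-9)

    def test_alpha_zero_reduces_to_preliminary(self, rng):
        for _ in range(10):
            mix = random_com_mixture(rng)
            p = cr.ObserverParams(sigma_rho=0.06, alpha=0.0, sigma_adj=2.8)
            assert cr.adjusted_endpoint(mix, 1.5, p) == cr.preliminary_endpoint(mix)

    def test_huge_alpha_pins_endpoint_at_r0(self):
        mix = cr.GaussianMixture1D([1.0], [0.0], [0.5], space="com")
        p = cr.ObserverParams(sigma_rho=0.06, alpha=1e9, sigma_adj=2.8)
        assert cr.adjusted_endpoint(mix, 1.5, p) == pytest.approx(1.5, abs=5e-3)

    def test_partial_correction_between_targets(self):
        mix = cr.GaussianMixture1D([1.0], [0.0], [0.54], space="com")
        p = cr.ObserverParams(sigma_rho=0.063, alpha=3.1, sigma_adj=2.8)
        s = cr.adjusted_endpoint(mix, 1.5, p)
        assert 0.0 < s < 1.5
        assert s == pytest.approx(grid_oracle_adj(mix, 1.5, p), abs=2e-3)

    def test_monotone_in_alpha(self, rng):
        for _ in range(15):
            mix = random_com_mixture(rng)
            r0 = rng.uniform(-4, 4)
            prev = None
            for alpha in (0.0, 0.5, 2.0, 8.0, 50.0):
                p = cr.ObserverParams(sigma_rho=0.06, alpha=alpha, sigma_adj=2.8)
                d = abs(cr.adjusted_endpoint(mix, r0, p) - r0)
                if prev is not None:
                    assert d <= prev + 2e-3
                prev = d

    def test_uncorrected_fraction_grows_with_posterior_width(self):
        # The core mechanism: wider posteriors make corrections less
        # valuable, so more of the perturbation is left uncorrected.
        p = cr.ObserverParams(sigma_rho=0.063, alpha=3.1, sigma_adj=2.8)
        residuals = []
        for sd in (0.05, 0.2, 0.54, 1.0, 1.8):
            mix = cr.GaussianMixture1D([1.0], [0.0], [sd], space="com")
            residuals.append(cr.adjusted_endpoint(mix, 1.5, p))
        assert all(b > a - 1e-9 for a, b in zip(residuals, residuals[1:]))
        assert residuals[-1] > residuals[0]

    def test_rejects_nonfinite_r0(self):
        mix = cr.GaussianMixture1D([1.0], [0.0], [0.5], space="com")
        p = cr.ObserverParams(sigma_rho=0.06, alpha=1.0, sigma_adj=2.8)
        with pytest.raises(ValueError):
            cr.adjusted_endpoint(mix, math.nan, p)


class TestResponseDistribution:
    def test_normalizes_for_random_parameters(self, rng):
        for _ in range(5):
            p = cr.ObserverParams(
                sigma_rho=rng.uniform(0.02, 0.15),
                dim_d=rng.uniform(1.0, 3.0),
                alpha=rng.uniform(0, 5),
                sigma_adj=rng.uniform(1.0, 5.0),
                sigma_motor=rng.uniform(0.3, 1.5),
            )
            dist = cr.response_distribution(rng.uniform(-0.6, 0.6), rng.uniform(-2, 2), p)
            r = np.linspace(-25, 25, 12001)  # response support extends past the bar
            assert np.trapezoid(dist.pdf(r), r) == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_measurement_concentrates_at_map(self):
        p = cr.ObserverParams(sigma_rho=1e-8, dim_d=2.0, alpha=0.0, sigma_motor=0.4)
        rho = math.log(1.5)
        dist = cr.response_distribution(rho, 0.0, p)
        target = cr.com_map(rho, 2.0)
        assert dist.mean() == pytest.approx(target, abs=1e-3)
        assert dist.pdf(target) == pytest.approx(stats.norm.pdf(0, 0, 0.4), rel=1e-3)

    def test_zero_motor_noise_density_rejected(self):
        p = cr.ObserverParams(sigma_rho=0.06, sigma_motor=0.0)
        dist = cr.response_distribution(0.0, 0.0, p)
        with pytest.raises(ValueError):
            dist.pdf(0.0)

    def test_mean_shift_matches_decision_path(self, group_params):
        # Mean response shift under perturbation equals the quadrature mean
        # of the adjusted endpoints (Monte Carlo vs deterministic oracle).
        rho, b = math.log(1.5), 1.5
        dist = cr.response_distribution(rho, b, group_params)
        dist0 = cr.response_distribution(rho, 0.0, group_params)
        rng = np.random.default_rng(5)
        shift_mc = dist.sample(40000, rng).mean() - dist0.sample(40000, rng).mean()
        shift_det = dist.mean() - dist0.mean()
        assert shift_mc == pytest.approx(shift_det, abs=0.02)


class TestExpectedScore:
    def test_perfect_observer_scores_maximum(self):
        p = cr.ObserverParams(sigma_rho=1e-7, dim_d=2.0, alpha=0.0, sigma_motor=0.0)
        mean, se = cr.expected_score(p, "high", 2000, 7)
        assert mean == pytest.approx(10.0, abs=0.01)

    def test_gaussian_error_closed_form(self, rng):
        # Pure Gaussian response error: the continuous-score mean has the
        # closed form max * s0 / sqrt(s0^2 + sigma^2).
        from comreach.task_synthetic import score

        for sigma in (0.4, 1.02):
            ds = rng.normal(0, sigma, 200_000)
            got = score(ds).mean()
            assert got == pytest.approx(cr.gaussian_score_mean(sigma), abs=0.1)

    def test_validates_inputs(self):
        p = cr.ObserverParams(sigma_rho=0.06)
        with pytest.raises(ValueError):
            cr.expected_score(p, "medium", 100, 0)
        with pytest.raises(ValueError):
            cr.expected_score(p, "low", 0, 0)


class TestTypes:
    def test_mixture_validation(self):
        with pytest.raises(ValueError):
            cr.GaussianMixture1D([0.5, 0.6], [0, 1], [1, 1])
        with pytest.raises(ValueError):
            cr.GaussianMixture1D([1.0], [0.0], [-0.1])
        with pytest.raises(ValueError):
            cr.GaussianMixture1D([1.0], [0.0], [1.0], space="x")

    def test_params_validation(self):
        with pytest.raises(ValueError):
            cr.ObserverParams(sigma_rho=0.0)
        with pytest.raises(ValueError):
            cr.ObserverParams(sigma_rho=0.1, dim_d=-1)
        with pytest.raises(ValueError):
            cr.ObserverParams(sigma_rho=0.1, alpha=-0.5)
        p = cr.ObserverParams(sigma_rho=0.1, sigma_adj=math.inf)
        assert p.inv_sigma_adj == 0.0

    def test_prior_matches_experimental_statistics(self, prior):
        np.testing.assert_allclose(prior.weights, [1 / 3] * 3)
        np.testing.assert_allclose(prior.means, [-math.log(1.5), 0, math.log(1.5)])
        np.testing.assert_allclose(prior.sds, [0.1, 0.0, 0.1])
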