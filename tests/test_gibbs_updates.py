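"""Exact-conditional checks of each Gibbs block against independent oracles."""

import numpy as np
import pytest

from mazelearn.gibbs import (
    SamplerConfig,
    init_chain,
    sample_truncnorm_lower,
    update_fixed_effects,
    update_latent,
    update_random_effects,
    update_variance_components,
)
from oracles import (
    grid_posterior,
    grid_quantile,
    make_state,
    manual_design,
    truncnorm_lower_mean,
    truncnorm_lower_sd,
)


class TestLatentUpdate:
    def test_no_censoring_is_a_noop(self):
        d = manual_design(np.ones((5, 1)), [10, 20, 30, 40, 50], [False] * 5)
        s = make_state(d, beta=[30.0], sd_residual=5.0)
        before = s.ystar.copy()
        update_latent(s, d)
        np.testing.assert_array_equal(s.ystar, before)

    def test_redraws_respect_truncation_bound(self, rng):
        n = 100_000
        d = manual_design(np.ones((n, 1)), np.full(n, 60.0), [True] * n)
        s = make_state(d, beta=[55.0], sd_residual=10.0, seed=1)
        update_latent(s, d)
        assert (s.ystar >= 60.0).all()

    def test_mean_matches_closed_form(self):
        n = 100_000
        mu, sigma, bound = 55.0, 10.0, 60.0
        d = manual_design(np.ones((n, 1)), np.full(n, bound), [True] * n)
        s = make_state(d, beta=[mu], sd_residual=sigma, seed=2)
        update_latent(s, d)
        target = truncnorm_lower_mean(mu, sigma, bound)
        se = truncnorm_lower_sd(mu, sigma, bound) / np.sqrt(n)
        assert abs(s.ystar.mean() - target) < 3 * se

    def test_far_tail_is_finite_and_bounded(self):
        # bound 40 residual sd away from the mean: tail mass underflows,
        # the exponential fallback must still produce valid draws
        n = 1000
        d = manual_design(np.ones((n, 1)), np.full(n, 60.0), [True] * n)
        s = make_state(d, beta=[20.0], sd_residual=1.0, seed=3)
        update_latent(s, d)
        assert np.isfinite(s.ystar).all()
        assert (s.ystar >= 60.0).all()


class TestFixedEffectsUpdate:
    def test_degenerate_sigma_limit_concentrates_at_least_squares(self):
        X = np.column_stack([np.ones(5), [1, 2, 3, 4, 5]])
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.9])
        d = manual_design(X, y, [False] * 5)
        beta_ls = np.linalg.lstsq(X, y, rcond=None)[0]
        s = make_state(d, beta=[0.0, 0.0], sd_residual=1e-7, seed=4)
        update_fixed_effects(s, d)
        np.testing.assert_allclose(s.beta, beta_ls, atol=1e-5)

    def test_conjugate_posterior_intercept_only(self):
        # flat prior, known sigma, y = {1,2,3}: posterior is N(2, sigma^2/3)
        sigma = 1.5
        d = manual_design(np.ones((3, 1)), [1.0, 2.0, 3.0], [False] * 3)
        s = make_state(d, beta=[0.0], sd_residual=sigma, seed=5)
        n_draws = 20_000
        draws = np.empty(n_draws)
        for i in range(n_draws):
            update_fixed_effects(s, d)
            draws[i] = s.beta[0]
        post_sd = sigma / np.sqrt(3)
        assert abs(draws.mean() - 2.0) < 3 * post_sd / np.sqrt(n_draws)
        assert abs(draws.std(ddof=1) - post_sd) < 3 * post_sd / np.sqrt(2 * n_draws)

    def test_two_parameter_grid_integration_oracle(self):
        X = np.column_stack([np.ones(5), [-2.0, -1.0, 0.0, 1.0, 2.0]])
        y = np.array([3.1, 4.0, 5.2, 5.8, 7.1])
        sigma = 1.0
        d = manual_design(X, y, [False] * 5)
        s = make_state(d, beta=[0.0, 0.0], sd_residual=sigma, seed=6)
        n_draws = 40_000
        draws = np.empty((n_draws, 2))
        for i in range(n_draws):
            update_fixed_effects(s, d)
            draws[i] = s.beta
        # dense 2-D grid posterior under the flat prior
        b0 = np.linspace(3.0, 7.0, 161)
        b1 = np.linspace(0.0, 2.0, 161)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        ll = np.zeros_like(B0)
        for xi, yi in zip(X, y):
            ll += -((yi - B0 * xi[0] - B1 * xi[1]) ** 2) / (2 * sigma**2)
        w = np.exp(ll - ll.max())
        w /= w.sum()
        oracle = np.array([(w * B0).sum(), (w * B1).sum()])
        np.testing.assert_allclose(draws.mean(axis=0), oracle, atol=0.01)


class TestRandomEffectsUpdate:
    def _design_one_mouse(self, n=8, yval=5.0):
        X = np.ones((n, 1))
        Zrow = np.zeros((n, 4))
        Zrow[:, 0] = 1.0  # intercept-only random structure
        return manual_design(X, np.full(n, yval), [False] * n, Zrow=Zrow)

    def test_shrinkage_limit_zero_sds(self):
        d = self._design_one_mouse()
        s = make_state(d, beta=[0.0], sd_residual=1.0,
                       sd_intercept=1e-8, sd_spline=(1e-8, 1e-8, 1e-8), seed=7)
        update_random_effects(s, d)
        assert np.abs(s.b).max() < 1e-6

    def test_one_dimensional_conjugate_shrinkage_formula(self):
        n, yval, sigma, tau = 8, 5.0, 2.0, 3.0
        d = self._design_one_mouse(n, yval)
        s = make_state(d, beta=[1.0], sd_residual=sigma,
                       sd_intercept=tau, sd_spline=(1e-9, 1e-9, 1e-9), seed=8)
        resid_sum = n * (yval - 1.0)
        prec = n / sigma**2 + 1 / tau**2
        target_mean = (resid_sum / sigma**2) / prec
        target_sd = 1 / np.sqrt(prec)
        n_draws = 20_000
        draws = np.empty(n_draws)
        for i in range(n_draws):
            update_random_effects(s, d)
            draws[i] = s.b[0, 0]
        assert abs(draws.mean() - target_mean) < 3 * target_sd / np.sqrt(n_draws)
        assert abs(draws.std(ddof=1) - target_sd) < 3 * target_sd / np.sqrt(2 * n_draws)

    def test_mouse_permutation_leaves_conditionals_unchanged(self):
        rng = np.random.default_rng(9)
        n, m = 60, 5
        X = np.ones((n, 1))
        y = rng.normal(30, 8, n)
        Zrow = np.zeros((n, 4))
        Zrow[:, 0] = 1.0
        Zrow[:, 1] = rng.normal(size=n)
        midx = rng.integers(0, m, n)
        d1 = manual_design(X, y, [False] * n, Zrow=Zrow, mouse_index=midx)

        perm = rng.permutation(m)
        d2 = manual_design(X, y, [False] * n, Zrow=Zrow, mouse_index=perm[midx])

        class ZeroRng:
            def standard_normal(self, shape):
                return np.zeros(shape)

        means = []
        for d in (d1, d2):
            s = make_state(d, beta=[25.0], sd_residual=5.0,
                           sd_intercept=4.0, sd_spline=(2.0, 2.0, 2.0))
            s.rng = ZeroRng()
            update_random_effects(s, d)  # zero noise => draw == conditional mean
            means.append(s.b)
        np.testing.assert_allclose(means[0], means[1][perm], atol=1e-12)


class TestVarianceComponentUpdate:
    def test_conditional_matches_grid_of_flat_sd_density(self):
        # u = (1, -1, 2, 0), M = 4: density of sigma^2 is proportional to
        # sigma^{-(M+1)} exp(-sum u^2 / (2 sigma^2))
        u = np.array([1.0, -1.0, 2.0, 0.0])
        d = manual_design(np.ones((4, 1)), [0.0] * 4, [False] * 4,
                          Zrow=np.tile([1.0, 0, 0, 0], (4, 1)),
                          mouse_index=np.arange(4))
        pinned = ("sd_spline1", "sd_spline2", "sd_spline3", "sd_residual")
        s = make_state(d, beta=[0.0], sd_residual=1.0, seed=10, fixed=pinned)
        s.b[:, 0] = u
        n_draws = 200_000
        draws = np.empty(n_draws)
        for i in range(n_draws):
            update_variance_components(s, d)
            draws[i] = s.sd_intercept**2
        ss = float((u**2).sum())
        # log-spaced grid: the inverse-gamma tail is heavy and must be covered
        grid = np.geomspace(1e-3, 5e3, 400_000)
        logpost = lambda v: -(len(u) + 1) / 2 * np.log(v) - ss / (2 * v)
        lp = logpost(grid)
        w = np.exp(lp - lp.max())
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        for q in np.arange(0.1, 0.95, 0.1):
            target = grid_quantile(cdf, grid, q)
            achieved = np.quantile(draws, q)
            assert abs(achieved - target) / target < 0.01, f"quantile {q}"

    def test_all_zero_effects_guarded_by_floor(self, caplog):
        d = manual_design(np.ones((4, 1)), [0.0] * 4, [False] * 4,
                          Zrow=np.tile([1.0, 0, 0, 0], (4, 1)),
                          mouse_index=np.arange(4))
        s = make_state(d, beta=[0.0], seed=11)
        s.b[:] = 0.0
        import logging

        with caplog.at_level(logging.WARNING, logger="mazelearn.gibbs"):
            update_variance_components(s, d)
        assert s.sd_intercept > 0
        assert "floored" in caplog.text

    def test_scale_equivariance_doubling_u_doubles_median(self):
        def median_for(u, seed):
            d = manual_design(np.ones((4, 1)), [0.0] * 4, [False] * 4,
                              Zrow=np.tile([1.0, 0, 0, 0], (4, 1)),
                              mouse_index=np.arange(4))
            pinned = ("sd_spline1", "sd_spline2", "sd_spline3", "sd_residual")
            s = make_state(d, beta=[0.0], seed=seed, fixed=pinned)
            s.b[:, 0] = u
            draws = np.empty(20_000)
            for i in range(len(draws)):
                update_variance_components(s, d)
                draws[i] = s.sd_intercept
            return np.median(draws)

        u = np.array([1.0, -1.0, 2.0, 0.5])
        ratio = median_for(2 * u, seed=13) / median_for(u, seed=12)
        assert abs(ratio - 2.0) < 0.06

    def test_too_few_mice_refused(self):
        d = manual_design(np.ones((2, 1)), [0.0, 0.0], [False, False],
                          Zrow=np.tile([1.0, 0, 0, 0], (2, 1)),
                          mouse_index=np.arange(2))
        s = make_state(d, beta=[0.0], seed=14)
        with pytest.raises(ValueError, match="improper"):
            update_variance_components(s, d)


class TestTruncnormSampler:
    def test_reduces_to_standard_normal_when_bound_is_far_left(self, rng):
        draws = sample_truncnorm_lower(rng, np.zeros(200_000), 1.0, -40.0)
        assert abs(draws.mean()) < 0.01
        assert abs(draws.std() - 1.0) < 0.01


class TestInitChain:
    def _design(self):
        rng = np.random.default_rng(15)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = 40 + rng.normal(0, 5, 30)
        cens = y >= 60
        y[cens] = 60.0
        return manual_design(X, y, cens)

    def test_overdispersed_starts_differ_by_chain(self):
        d = self._design()
        cfg = SamplerConfig(base_seed=3)
        s0, s1 = init_chain(d, cfg, 0), init_chain(d, cfg, 1)
        assert not np.allclose(s0.beta, s1.beta)
        assert s0.rng.bit_generator.state != s1.rng.bit_generator.state

    def test_same_seed_and_chain_is_bit_identical(self):
        d = self._design()
        cfg = SamplerConfig(base_seed=3)
        a, b = init_chain(d, cfg, 1), init_chain(d, cfg, 1)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.ystar, b.ystar)
        assert a.sds().tolist() == b.sds().tolist()
        assert a.rng.bit_generator.state == b.rng.bit_generator.state

    def test_uncensored_data_initializes_latents_at_observations(self):
        rng = np.random.default_rng(16)
        X = np.ones((10, 1))
        y = rng.uniform(10, 50, 10)
        d = manual_design(X, y, [False] * 10)
        s = init_chain(d, SamplerConfig(), 0)
        np.testing.assert_array_equal(s.ystar, y)

    def test_censored_latents_start_above_cutoff(self):
        d = self._design()
        s = init_chain(d, SamplerConfig(), 2)
        assert (s.ystar[d.censored_idx] == 61.0).all()
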