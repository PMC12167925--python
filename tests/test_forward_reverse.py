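"""Forward process, posterior, and reverse sampler against independent oracles.

Oracles: brute-force Monte-Carlo chaining of the per-step kernel (vs the
closed-form marginal), and a discretized-Bayes numerical posterior (vs the
analytic product-of-Gaussians posterior).
"""

import numpy as np
import pytest

import residiff as rd
from residiff.schedule import (
    DiffusionState,
    PairedSample,
    ScheduleConfigError,
    forward_marginal,
    forward_step,
    init_sample,
    posterior_params,
    reverse_step,
    sample,
)
from conftest import oracle_denoiser


def numerical_posterior(sched, t_hi, t_lo, x0, e0, x_hi, n_grid=200_001, span=8.0):
    """Discretized-Bayes oracle for the scalar posterior q(x_lo | x_hi, x0).

    Tabulates q(x_lo | x0) * q(x_hi | x_lo) on a fine grid and returns the
    normalized mean and variance.  Entirely independent of the analytic
    posterior formula.
    """
    g = sched.gamma
    b_hi, b_lo = sched.beta_at(t_hi), sched.beta_at(t_lo)
    mu_marg = x0 + b_lo * e0
    sd_marg = g * np.sqrt(b_lo)
    mu_step_shift = (b_hi - b_lo) * e0
    sd_step = g * np.sqrt(b_hi - b_lo)
    lo = min(mu_marg, x_hi - mu_step_shift) - span * max(sd_marg, sd_step)
    hi = max(mu_marg, x_hi - mu_step_shift) + span * max(sd_marg, sd_step)
    x = np.linspace(lo, hi, n_grid)
    logp = -0.5 * ((x - mu_marg) / sd_marg) ** 2 - 0.5 * ((x_hi - x - mu_step_shift) / sd_step) ** 2
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean = float((w * x).sum())
    var = float((w * (x - mean) ** 2).sum())
    return mean, var


class TestForwardStep:
    def test_zero_residual_zero_noise_is_identity(self, default_schedule):
        x = np.random.default_rng(0).random((4, 4)).astype(np.float32)
        out = forward_step(x, np.zeros_like(x), default_schedule, t=5, noise=np.zeros_like(x))
        np.testing.assert_array_equal(out, x)

    def test_deterministic_drift_term(self, default_schedule):
        rng = np.random.default_rng(1)
        x = rng.random((4, 4)).astype(np.float32)
        e0 = rng.random((4, 4)).astype(np.float32)
        t = 7
        out = forward_step(x, e0, default_schedule, t, noise=np.zeros_like(x))
        expected = x + np.float32(default_schedule.alpha_at(t)) * e0
        np.testing.assert_allclose(out, expected, atol=1e-7)

    def test_step_out_of_range(self, default_schedule):
        x = np.zeros((2, 2), dtype=np.float32)
        with pytest.raises(IndexError):
            forward_step(x, x, default_schedule, t=16, noise=x)

    @pytest.mark.parametrize("t_target", [1, 7, 15])
    def test_chained_moments_match_closed_form(self, default_schedule, t_target):
        """Iterated per-step kernel reproduces the marginal mean/variance."""
        sched = default_schedule
        n_draws = 100_000
        rng = np.random.default_rng(42)
        x0, e0 = 0.3, 0.4
        x = np.full(n_draws, x0)
        for t in range(1, t_target + 1):
            x = forward_step(x, np.full(n_draws, e0), sched, t, rng.standard_normal(n_draws))
        b = sched.beta_at(t_target)
        exp_mean = x0 + b * e0
        exp_var = sched.gamma**2 * b
        se_mean = np.sqrt(exp_var / n_draws)
        assert abs(x.mean() - exp_mean) < 3 * se_mean
        assert 0.97 < x.var() / exp_var < 1.03


class TestForwardMarginal:
    def test_terminal_step_lands_near_lr(self, default_schedule):
        pair = rd.make_phantom(rd.PhantomSpec(size=32, seed=1))
        state = forward_marginal(pair, default_schedule, t=15, noise=np.zeros_like(pair.x_hr))
        bound = (1 - default_schedule.beta_T) * np.abs(pair.e0).max()
        assert np.abs(state.x_t - pair.x_lr).max() <= bound + 1e-6

    def test_degenerate_pair_is_fixed_point(self, default_schedule):
        x = np.random.default_rng(2).random((8, 8)).astype(np.float32)
        pair = PairedSample(x_hr=x, x_lr=x.copy())
        for t in (1, 7, 15):
            state = forward_marginal(pair, default_schedule, t, noise=np.zeros_like(x))
            np.testing.assert_allclose(state.x_t, x, atol=1e-7)
            assert state.t == t

    def test_stochastic_moments_per_pixel(self, default_schedule):
        """Sample mean and variance over many draws on a 2x2 image."""
        sched = default_schedule
        pair = PairedSample(
            x_hr=np.array([[0.1, 0.5], [0.3, 0.9]], dtype=np.float32),
            x_lr=np.array([[0.2, 0.4], [0.6, 0.1]], dtype=np.float32),
        )
        t, n_draws = 7, 100_000
        rng = np.random.default_rng(7)
        draws = np.stack(
            [forward_marginal(pair, sched, t, rng.standard_normal((2, 2))).x_t for _ in range(n_draws)]
        ).astype(np.float64)
        b = sched.beta_at(t)
        exp_mean = pair.x_hr + b * pair.e0
        exp_var = sched.gamma**2 * b
        se = np.sqrt(exp_var / n_draws)
        assert np.abs(draws.mean(axis=0) - exp_mean).max() < 3.5 * se
        assert np.all((draws.var(axis=0) / exp_var > 0.97) & (draws.var(axis=0) / exp_var < 1.03))


class TestPosterior:
    def test_final_step_collapses_to_denoiser_estimate(self, default_schedule):
        rng = np.random.default_rng(3)
        x_t = rng.random((4, 4)).astype(np.float32)
        x0_hat = rng.random((4, 4)).astype(np.float32)
        post = posterior_params(x_t, x0_hat, default_schedule, t_hi=1, t_lo=0)
        np.testing.assert_array_equal(post.mean, x0_hat)
        assert post.var == 0.0

    def test_noise_free_trajectory_identity(self, default_schedule):
        """x_t built as x0 + beta_hi e0 maps to x0 + beta_lo e0 exactly."""
        rng = np.random.default_rng(4)
        x0 = rng.random((4, 4))
        e0 = rng.random((4, 4)) - 0.5
        for t_hi, t_lo in [(15, 14), (15, 11), (7, 3), (3, 1)]:
            x_t = x0 + default_schedule.beta_at(t_hi) * e0
            post = posterior_params(x_t, x0, default_schedule, t_hi, t_lo)
            expected = x0 + default_schedule.beta_at(t_lo) * e0
            np.testing.assert_allclose(post.mean, expected, atol=1e-6)

    def test_ordering_violation(self, default_schedule):
        x = np.zeros((2, 2))
        with pytest.raises(ValueError):
            posterior_params(x, x, default_schedule, t_hi=3, t_lo=3)

    @pytest.mark.parametrize("t_hi,t_lo", [(t, t - 1) for t in range(2, 16)])
    def test_adjacent_posterior_matches_discretized_bayes(self, default_schedule, t_hi, t_lo):
        x0, e0, x_hi = 0.3, 0.5, 0.9
        mean_num, var_num = numerical_posterior(default_schedule, t_hi, t_lo, x0, e0, x_hi)
        post = posterior_params(np.array(x_hi), np.array(x0), default_schedule, t_hi, t_lo)
        assert float(post.mean) == pytest.approx(mean_num, abs=1e-3)
        assert post.var == pytest.approx(var_num, abs=1e-3)

    @pytest.mark.parametrize("t_hi,t_lo", [(15, 11), (11, 7), (7, 3)])
    def test_skip_step_posterior_matches_discretized_bayes(self, default_schedule, t_hi, t_lo):
        x0, e0, x_hi = 0.2, -0.4, 0.6
        mean_num, var_num = numerical_posterior(default_schedule, t_hi, t_lo, x0, e0, x_hi)
        post = posterior_params(np.array(x_hi), np.array(x0), default_schedule, t_hi, t_lo)
        assert float(post.mean) == pytest.approx(mean_num, abs=1e-3)
        assert post.var == pytest.approx(var_num, abs=1e-3)


class TestInitSample:
    def test_zero_noise_starts_at_lr(self, default_schedule):
        x_lr = np.random.default_rng(5).random((4, 4)).astype(np.float32)
        state = init_sample(x_lr, default_schedule, np.zeros_like(x_lr))
        np.testing.assert_array_equal(state.x_t, x_lr)
        assert state.t == 15

    def test_unit_noise_direct_substitution(self, default_schedule):
        x_lr = np.zeros((2, 2), dtype=np.float32)
        state = init_sample(x_lr, default_schedule, np.ones_like(x_lr))
        np.testing.assert_allclose(state.x_t, 2.0 * np.sqrt(0.9999), rtol=1e-6)

    def test_init_variance_matches_terminal_kernel(self, default_schedule):
        n = 100_000
        rng = np.random.default_rng(6)
        draws = np.stack(
            [init_sample(np.zeros(1, dtype=np.float32), default_schedule, rng.standard_normal(1)).x_t
             for _ in range(n)]
        )
        exp_var = default_schedule.gamma**2 * default_schedule.beta_T
        assert 0.97 < draws.var() / exp_var < 1.03


class TestReverseAndSample:
    def test_single_step_to_zero_ignores_noise(self, default_schedule):
        rng = np.random.default_rng(8)
        state = DiffusionState(x_t=rng.random((4, 4)).astype(np.float32), t=1)
        x0_hat = rng.random((4, 4)).astype(np.float32)
        out = reverse_step(state, x0_hat, default_schedule, 0, rng.standard_normal((4, 4)))
        np.testing.assert_array_equal(out.x_t, x0_hat)

    @pytest.mark.parametrize("grid", [list(range(15, -1, -1)), [15, 11, 7, 3, 0]])
    def test_perfect_denoiser_recovers_hr(self, default_schedule, phantom64, grid):
        out = sample(
            phantom64.x_lr, oracle_denoiser(phantom64), default_schedule,
            step_grid=grid, stochastic=False,
        )
        assert np.abs(out - phantom64.x_hr).max() <= 1e-5

    def test_identical_seeds_bit_identical(self, default_schedule, phantom32):
        den = lambda x_t, x_lr, t: np.clip(0.5 * (x_t + x_lr), 0, 1)
        a = sample(phantom32.x_lr, den, default_schedule, seed=9)
        b = sample(phantom32.x_lr, den, default_schedule, seed=9)
        np.testing.assert_array_equal(a, b)
        c = sample(phantom32.x_lr, den, default_schedule, seed=10)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("grid", [[14, 7, 0], [15, 7], [15, 8, 8, 0]])
    def test_invalid_grids_rejected(self, default_schedule, phantom32, grid):
        with pytest.raises(ScheduleConfigError):
            sample(phantom32.x_lr, oracle_denoiser(phantom32), default_schedule, step_grid=grid)
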