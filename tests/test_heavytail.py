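"""Tests for alpha-stable sampling, SDE simulators, tail estimation, KDE."""

import math

import numpy as np
import pytest
from scipy import stats

from stdptail.heavytail import (
    KDEConfig,
    StableSpec,
    bg_index,
    estimate_tail_index,
    kde_pdf,
    sample_alpha_stable,
    silverman_bandwidth,
    simulate_membrane_sde,
    simulate_ou_levy,
)


class TestStableSampler:
    def test_gaussian_reduction_at_alpha_two(self):
        x = sample_alpha_stable(StableSpec(alpha=2.0, scale=1.5, n=200_000, seed=0))
        assert x.var() == pytest.approx(2 * 1.5**2, rel=0.02)
        assert x.mean() == pytest.approx(0.0, abs=0.02)

    def test_cauchy_reduction_at_alpha_one(self):
        x = sample_alpha_stable(StableSpec(alpha=1.0, scale=2.0, n=200_000, seed=1))
        assert np.median(x) == pytest.approx(0.0, abs=0.05)
        # Cauchy(scale) quartiles are +-scale
        q25, q75 = np.percentile(x, [25, 75])
        assert q75 == pytest.approx(2.0, rel=0.05)
        assert q25 == pytest.approx(-2.0, rel=0.05)

    def test_seed_determinism(self):
        a = sample_alpha_stable(StableSpec(alpha=1.5, scale=1.0, n=100, seed=9))
        b = sample_alpha_stable(StableSpec(alpha=1.5, scale=1.0, n=100, seed=9))
        np.testing.assert_array_equal(a, b)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            StableSpec(alpha=0.0)
        with pytest.raises(ValueError):
            StableSpec(alpha=2.5)

    def test_matches_scipy_levy_stable(self):
        """KS test against scipy's independent alpha-stable implementation."""
        alpha = 1.5
        x = sample_alpha_stable(StableSpec(alpha=alpha, scale=1.0, n=2000, seed=3))
        dist = stats.levy_stable(alpha, 0.0)
        res = stats.kstest(x, dist.cdf)
        assert res.pvalue > 0.01


class TestOULevy:
    def test_gaussian_ou_stationary_variance(self):
        theta, scale, dt = 0.5, 1.0, 0.01
        x = simulate_ou_levy(2.0, theta, scale, n_steps=200_000, dt=dt, seed=0)
        stationary = x[50_000:, 0]
        # dX = -theta X dt + scale sqrt(dt) L, var(L)=2 -> var = scale^2 / theta
        assert stationary.var() == pytest.approx(scale**2 / theta, rel=0.1)

    def test_zero_drift_variance_grows_linearly(self):
        x = simulate_ou_levy(2.0, 0.0, 1.0, n_steps=4000, dt=0.01, dims=200, seed=1)
        v_half = x[2000].var()
        v_full = x[4000].var()
        assert v_full / v_half == pytest.approx(2.0, rel=0.2)

    def test_tail_weight_increases_as_alpha_drops(self):
        """Heavier increments (excess mass beyond 10 MAD) as alpha falls.

        Raw sample kurtosis diverges for alpha < 2, so the ordering is
        asserted on a robust tail-mass statistic instead; the Gaussian
        end is additionally checked to have (finite) near-zero kurtosis.
        """
        tail_mass = []
        for k, alpha in enumerate((2.0, 1.7, 1.4, 1.1)):
            x = simulate_ou_levy(alpha, 0.1, 1.0, n_steps=20_000, dt=0.01, seed=10 + k)
            inc = np.diff(x[:, 0])
            mad = np.median(np.abs(inc - np.median(inc)))
            tail_mass.append(np.mean(np.abs(inc) > 10 * mad))
        assert all(a < b for a, b in zip(tail_mass, tail_mass[1:]))
        gauss_inc = np.diff(
            simulate_ou_levy(2.0, 0.1, 1.0, n_steps=20_000, dt=0.01, seed=10)[:, 0]
        )
        assert abs(stats.kurtosis(gauss_inc)) < 0.2

    def test_three_dimensional_trajectories(self):
        x = simulate_ou_levy(1.4, 0.05, 1.0, n_steps=100, dt=0.01, dims=3, seed=2)
        assert x.shape == (101, 3)

    def test_negative_drift_rejected(self):
        with pytest.raises(ValueError):
            simulate_ou_levy(1.5, -0.1, 1.0, n_steps=10, dt=0.01)


class TestMembraneSDE:
    def test_shot_noise_stationary_mean(self):
        """With no post-spiking, E[X] -> W * lambda * tau."""
        W, lam, tau = 0.5, 0.2, 20.0
        _, path, _ = simulate_membrane_sde(W, lam, tau, T=60_000.0, dt=0.1, seed=0)
        stat = path[len(path) // 4 :]
        want = W * lam * tau
        se = stat.std() / math.sqrt(len(stat) / (tau / 0.1))  # effective samples
        assert stat.mean() == pytest.approx(want, abs=max(4 * se, 0.05 * want))

    def test_pure_exponential_decay_without_input(self):
        tau, dt, x0 = 15.0, 0.5, 3.0
        t, path, _ = simulate_membrane_sde(1.0, 0.0, tau, T=30.0, dt=dt, seed=1, x0=x0)
        np.testing.assert_allclose(path, x0 * np.exp(-t / tau), rtol=1e-10)

    def test_zero_is_fixed_point(self):
        _, path, spikes = simulate_membrane_sde(
            0.0, 5.0, 10.0, beta_fn=lambda x: max(x, 0.0), T=100.0, dt=0.1, seed=2
        )
        assert np.all(path == 0.0)
        assert len(spikes) == 0

    def test_post_spikes_reduce_mean(self):
        W, lam, tau = 0.5, 0.2, 20.0
        _, free, _ = simulate_membrane_sde(W, lam, tau, T=20_000.0, dt=0.1, seed=3)
        _, gated, spikes = simulate_membrane_sde(
            W, lam, tau, beta_fn=lambda x: 0.05 * max(x, 0.0), T=20_000.0, dt=0.1, seed=3
        )
        assert len(spikes) > 0
        assert gated.mean() < free.mean()


class TestTailIndexEstimator:
    @pytest.mark.parametrize(
        "alpha, lo, hi",
        [(2.0, 1.9, 2.0), (1.0, 0.9, 1.1), (1.5, 1.4, 1.6)],
    )
    def test_recovers_known_alpha(self, alpha, lo, hi):
        rng = np.random.default_rng(0)
        vals = []
        for k in range(20):
            x = sample_alpha_stable(StableSpec(alpha=alpha, scale=1.0, n=100_000), rng)
            vals.append(estimate_tail_index(x))
        mean = float(np.mean(vals))
        assert lo <= mean <= hi

    def test_mean_absolute_error_and_rank_ordering(self):
        """MAE <= 0.1 per alpha and perfect rank ordering of the means."""
        alphas = (1.1, 1.4, 1.7, 2.0)
        means = []
        for j, alpha in enumerate(alphas):
            rng = np.random.default_rng(100 + j)
            ests = [
                estimate_tail_index(
                    sample_alpha_stable(StableSpec(alpha=alpha, scale=1.0, n=100_000), rng)
                )
                for _ in range(20)
            ]
            assert np.mean(np.abs(np.array(ests) - alpha)) <= 0.1
            means.append(np.mean(ests))
        rho = stats.spearmanr(alphas, means).statistic
        assert rho == pytest.approx(1.0)

    def test_estimate_clipped_to_two(self):
        x = np.random.default_rng(1).uniform(-1, 1, 10_000)  # lighter than Gaussian
        assert estimate_tail_index(x) <= 2.0

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            estimate_tail_index(np.ones(10))

    def test_remainder_dropped_with_warning(self):
        x = np.random.default_rng(2).normal(size=1003)
        with pytest.warns(UserWarning, match="trailing"):
            estimate_tail_index(x, m=31)


class TestBGIndex:
    def _trajectory(self, final_inc, n_weights=None):
        final_inc = np.asarray(final_inc)
        base = np.zeros_like(final_inc)
        return np.vstack([base, base + final_inc])

    def test_single_group_is_identity(self):
        rng = np.random.default_rng(0)
        inc = sample_alpha_stable(StableSpec(alpha=1.2, scale=1.0, n=10_000), rng)
        rep = bg_index(self._trajectory(inc))
        assert rep.bg_index == rep.alpha_hat["input_to_exc"]

    def test_max_over_groups(self):
        rng = np.random.default_rng(3)
        heavy = sample_alpha_stable(StableSpec(alpha=1.1, scale=1.0, n=8_000), rng)
        light = rng.normal(size=8_000)
        snaps = self._trajectory(np.concatenate([heavy, light]))
        rep = bg_index(snaps, grouping={"a": np.arange(8_000), "b": np.arange(8_000, 16_000)})
        assert rep.bg_index == max(rep.alpha_hat.values())
        assert rep.alpha_hat["a"] < rep.alpha_hat["b"]

    def test_gaussian_increments_hit_upper_boundary(self):
        inc = np.random.default_rng(4).normal(size=40_000)
        rep = bg_index(self._trajectory(inc))
        assert rep.bg_index >= 1.9

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        inc = sample_alpha_stable(StableSpec(alpha=1.5, scale=1.0, n=20_000), rng)
        r1 = bg_index(self._trajectory(inc))
        r2 = bg_index(self._trajectory(1000.0 * inc))
        assert r1.bg_index == pytest.approx(r2.bg_index, rel=1e-9)
        assert 0 < r1.bg_index <= 2.0

    def test_constant_increments_flagged(self):
        snaps = np.vstack([np.zeros(5000), np.full(5000, 0.25)])
        with pytest.raises(ValueError, match="constant increments"):
            bg_index(snaps)

    def test_last_k_pooling(self):
        rng = np.random.default_rng(6)
        incs = [sample_alpha_stable(StableSpec(alpha=1.5, scale=1.0, n=9_000), rng) for _ in range(3)]
        snaps = np.cumsum(np.vstack([np.zeros(9_000)] + incs), axis=0)
        pooled = bg_index(snaps, last_k=3)
        single = bg_index(snaps, last_k=1)
        assert pooled.alpha_hat["input_to_exc"] == pytest.approx(1.5, abs=0.1)
        assert single.alpha_hat["input_to_exc"] == pytest.approx(1.5, abs=0.15)

    def test_requires_two_snapshots(self):
        with pytest.raises(ValueError):
            bg_index(np.zeros((1, 100)))


class TestKDE:
    def test_single_point_height(self):
        cfg = KDEConfig(t=1.0, grid=np.array([0.0]))
        got = kde_pdf([0.0], cfg)
        assert got[0] == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-12)
        assert got[0] == pytest.approx(0.39894, abs=1e-5)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        grid = np.linspace(-10, 10, 2001)
        pdf = kde_pdf(x, KDEConfig(t=0.5, grid=grid))
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetry(self):
        grid = np.linspace(-3, 3, 301)
        pdf = kde_pdf([-1.0, 1.0], KDEConfig(t=0.3, grid=grid))
        np.testing.assert_allclose(pdf, pdf[::-1], atol=1e-12)

    def test_bandwidth_to_zero_concentrates_mass(self):
        """sup of the density grows like t^{-1/2} as t -> 0."""
        grid = np.array([0.0])
        sups = [kde_pdf([0.0, 5.0], KDEConfig(t=t, grid=grid))[0] for t in (1.0, 0.01)]
        assert sups[1] / sups[0] == pytest.approx(math.sqrt(1.0 / 0.01), rel=1e-3)

    def test_matches_scipy_gaussian_kde(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        sk = stats.gaussian_kde(x)
        t = (sk.factor * x.std(ddof=1)) ** 2  # scipy bandwidth as variance
        grid = np.linspace(-3, 3, 50)
        ours = kde_pdf(x, KDEConfig(t=t, grid=grid))
        np.testing.assert_allclose(ours, sk(grid), rtol=1e-6)

    def test_silverman_bandwidth_positive(self):
        assert silverman_bandwidth(np.random.default_rng(0).normal(size=100)) > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kde_pdf([], KDEConfig(t=1.0, grid=np.array([0.0])))
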