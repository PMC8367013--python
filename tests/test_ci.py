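import numpy as np
import pytest

from ervar.ci import (
    bootstrap_ci,
    coverage_experiment,
    ecci,
    ecci_from_draws,
    log_posterior,
    posterior_draws,
    sample_estimator_given_r2,
    sufficient_stats,
)
from ervar.simulate import SimulationConfig, simulate_batch


class TestSufficientStats:
    def test_toy_values(self, toy_Y):
        s2, d2 = sufficient_stats(toy_Y)
        assert s2 == pytest.approx(2.0)
        assert d2 == pytest.approx(13.0 / 3.0)

    def test_constant_matrix(self):
        assert sufficient_stats(np.full((5, 3), 1.0)) == (0.0, 0.0)

    def test_expectations_match_sampling_distributions(self, rng):
        """s_hat^2 is unbiased for sigma^2; d_hat^2 carries the documented
        inflation m d^2/(m-1) + sigma^2/n."""
        m, n, sigma2, d2 = 25, 4, 0.25, 0.2
        cfg = SimulationConfig(m=m, n=n, sigma2=sigma2, d2=d2, r2_er_true=1.0, seed=17)
        Y = simulate_batch(cfg, 4000)
        ybar = Y.mean(axis=2)
        s2s = np.sum((Y - ybar[:, :, None]) ** 2, axis=(1, 2)) / (m * (n - 1))
        d2s = np.sum((ybar - ybar.mean(axis=1, keepdims=True)) ** 2, axis=1) / (m - 1)
        assert s2s.mean() == pytest.approx(sigma2, rel=0.02)
        expected_d2 = m * d2 / (m - 1) + sigma2 / n
        assert d2s.mean() == pytest.approx(expected_d2, rel=0.03)


def _grid_tv(sig, d2, s2h, d2h, m, n, bins=8, fine=12):
    """Total-variation distance between sample histogram and grid posterior."""
    s_edges = np.linspace(s2h * 0.5, s2h * 1.9, bins + 1)
    d_edges = np.linspace(0.0, d2h * 2.5, bins + 1)
    sf = np.linspace(s_edges[0], s_edges[-1], bins * fine + 1)
    df = np.linspace(d_edges[0], d_edges[-1], bins * fine + 1)
    sfc, dfc = 0.5 * (sf[1:] + sf[:-1]), 0.5 * (df[1:] + df[:-1])
    logp = np.array([[log_posterior(s, d, s2h, d2h, m, n) for d in dfc] for s in sfc])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_coarse = p.reshape(bins, fine, bins, fine).sum(axis=(1, 3))
    q, _, _ = np.histogram2d(sig, d2, bins=[s_edges, d_edges])
    q /= sig.size
    return 0.5 * np.abs(p_coarse - q).sum() + 0.5 * (1.0 - q.sum())


@pytest.fixture(scope="module")
def stats40():
    cfg = SimulationConfig(m=40, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.75, seed=5)
    Y = simulate_batch(cfg, 1)[0]
    return sufficient_stats(Y)


@pytest.fixture(scope="module")
def draws40(stats40):
    s2h, d2h = stats40
    return posterior_draws(s2h, d2h, 40, 4, 2000, seed=1)


@pytest.fixture(scope="module")
def npboot_dataset():
    from ervar.simulate import tuning_shape

    cfg = SimulationConfig(m=40, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.91, seed=41)
    return simulate_batch(cfg, 1)[0], tuning_shape(40, 0.91)[0]


class TestPosterior:
    def test_corrected_sampler_matches_grid_oracle(self, stats40):
        """Hastings-corrected chains reproduce the grid-evaluated posterior."""
        s2h, d2h = stats40
        parts = [
            posterior_draws(s2h, d2h, 40, 4, 5000, seed=k, hastings_correction=True)
            for k in range(3)
        ]
        sig = np.concatenate([c.sigma2 for c in parts])
        d2 = np.concatenate([c.d2 for c in parts])
        assert _grid_tv(sig, d2, s2h, d2h, 40, 4) < 0.1

    def test_plain_likelihood_rule_is_tighter_than_posterior(self, stats40):
        """The plain likelihood-ratio rule with an independence proposal has
        stationary law posterior x proposal — visibly narrower than the
        posterior itself.  Documented bias of the verbatim recipe."""
        s2h, d2h = stats40
        parts = [posterior_draws(s2h, d2h, 40, 4, 5000, seed=k) for k in range(3)]
        sig = np.concatenate([c.sigma2 for c in parts])
        d2 = np.concatenate([c.d2 for c in parts])
        tv_plain = _grid_tv(sig, d2, s2h, d2h, 40, 4)
        assert tv_plain > 0.1  # narrower-than-posterior inflation is real

    def test_high_information_posterior_centers_on_estimates(self):
        draws = posterior_draws(0.25, 0.5, 200, 50, 4000, seed=9, hastings_correction=True)
        assert abs(draws.sigma2.mean() - 0.25) / 0.25 < 0.05

    def test_deterministic_given_seed(self, stats40):
        s2h, d2h = stats40
        a = posterior_draws(s2h, d2h, 40, 4, 500, seed=3)
        b = posterior_draws(s2h, d2h, 40, 4, 500, seed=3)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)
        np.testing.assert_array_equal(a.d2, b.d2)

    def test_zero_variance_data_rejected(self):
        with pytest.raises(ValueError, match="improper"):
            posterior_draws(0.0, 1.0, 10, 4)


class TestEstimatorSampling:
    def test_zero_noise_draws_concentrate_at_candidate(self, draws40):
        from ervar.ci import PosteriorDraws

        tight = PosteriorDraws(
            np.full(500, 1e-12), np.full(500, 0.25), 500, 1.0
        )
        samples = sample_estimator_given_r2(0.6, tight, 40, 4, 500, rng=0)
        assert np.max(np.abs(samples - 0.6)) < 1e-3

    def test_cdf_monotone_in_candidate(self, draws40):
        """Stochastic-ordering assumption: F(obs | candidate) non-increasing."""
        obs = 0.7
        rng = np.random.default_rng(2)
        grid = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        ps = [
            np.mean(sample_estimator_given_r2(c, draws40, 40, 4, 4000, rng) <= obs)
            for c in grid
        ]
        assert np.all(np.diff(ps) <= 0.03)  # monotone up to Monte-Carlo jitter
        assert ps[0] > 0.9 and ps[-1] < 0.1

    def test_observed_estimate_self_consistency(self, draws40):
        """At the generating truth, the observed estimate falls inside the
        central 90% of the simulated distribution about 90% of the time."""
        rng = np.random.default_rng(3)
        ref = sample_estimator_given_r2(0.75, draws40, 40, 4, 4000, rng)
        lo, hi = np.quantile(ref, [0.05, 0.95])
        obs = sample_estimator_given_r2(0.75, draws40, 40, 4, 400, rng)
        frac = np.mean((obs >= lo) & (obs <= hi))
        assert 0.8 < frac < 0.97


class TestEcci:
    def test_zero_noise_perfect_model_interval(self):
        ybar = np.array([0.0, 1.0, 2.0, 4.0])
        Y = np.repeat(ybar[:, None], 3, axis=1)
        iv = ecci(1.0, Y, alpha=0.8, seed=0)
        assert (iv.low, iv.high) == (1.0, 1.0)
        assert iv.high_clamped and not iv.empty

    def test_deterministic_given_seed(self, rng):
        cfg = SimulationConfig(m=20, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.8, seed=31)
        Y = simulate_batch(cfg, 1)[0]
        kw = dict(alpha=0.8, seed=5, n_samples=600, chain_length=500)
        a = ecci(0.8, Y, **kw)
        b = ecci(0.8, Y, **kw)
        assert (a.low, a.high) == (b.low, b.high)

    def test_monotone_in_observed_estimate(self):
        cfg = SimulationConfig(m=20, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.5, seed=33)
        Y = simulate_batch(cfg, 1)[0]
        s2h, d2h = sufficient_stats(Y)
        draws = posterior_draws(s2h, d2h, 20, 4, 1500, seed=2)
        ivs = [
            ecci_from_draws(obs, draws, 20, 4, alpha=0.8, seed=7, n_samples=800)
            for obs in (0.2, 0.5, 0.9)
        ]
        lows = [iv.low for iv in ivs]
        highs = [iv.high for iv in ivs]
        assert lows == sorted(lows)
        assert highs == sorted(highs)

    def test_interval_within_unit_range(self):
        cfg = SimulationConfig(m=20, n=4, sigma2=0.25, d2=0.05, r2_er_true=0.5, seed=35)
        Y = simulate_batch(cfg, 1)[0]
        iv = ecci(0.5, Y, alpha=0.8, seed=1, n_samples=600, chain_length=800)
        assert 0.0 <= iv.low <= iv.high <= 1.0

    def test_full_coverage_level_gives_full_interval(self):
        cfg = SimulationConfig(m=20, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.5, seed=37)
        Y = simulate_batch(cfg, 1)[0]
        iv = ecci(0.5, Y, alpha=1.0, seed=1, n_samples=400, chain_length=400)
        assert (iv.low, iv.high) == (0.0, 1.0)


class TestBootstrap:
    @pytest.mark.parametrize("method", ["npboot", "pboot", "bca"])
    def test_interval_bounds_and_determinism(self, npboot_dataset, method):
        Y, nu = npboot_dataset
        a = bootstrap_ci(Y, nu, method, alpha=0.8, B=300, seed=9)
        b = bootstrap_ci(Y, nu, method, alpha=0.8, B=300, seed=9)
        assert (a.low, a.high) == (b.low, b.high)
        assert 0.0 <= a.low <= a.high <= 1.0

    @pytest.mark.parametrize("method", ["npboot", "pboot", "bca"])
    def test_zero_noise_gives_point_interval(self, method):
        ybar = np.array([0.0, 1.0, 3.0, 2.0])
        Y = np.repeat(ybar[:, None], 4, axis=1)
        iv = bootstrap_ci(Y, ybar, method, B=100, seed=0)
        assert iv.low == iv.high

    def test_npboot_sits_below_truth(self):
        """Non-parametric bootstrap intervals fall almost entirely below a
        high true correlation."""
        truth = 0.91
        cov = coverage_experiment(
            SimulationConfig(m=40, n=4, sigma2=0.25, d2=0.25, r2_er_true=truth, seed=43),
            ci_method="npboot", alpha=0.8, n_sims=40, seed=44, B=300,
        )
        uppers = np.array([iv.high for iv in cov.intervals])
        assert np.mean(uppers < truth) > 0.6
        assert cov.fraction < 0.6

    def test_pboot_coverage_beats_npboot(self):
        kw = dict(alpha=0.8, n_sims=40, B=300)
        cfg = lambda s: SimulationConfig(
            m=40, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.91, seed=s
        )
        np_cov = coverage_experiment(cfg(45), ci_method="npboot", seed=46, **kw)
        p_cov = coverage_experiment(cfg(45), ci_method="pboot", seed=46, **kw)
        assert abs(p_cov.fraction - 0.8) < abs(np_cov.fraction - 0.8)


class TestCoverage:
    def test_ecci_coverage_near_nominal_small_run(self):
        cov = coverage_experiment(
            SimulationConfig(m=40, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.5, seed=51),
            ci_method="ecci", alpha=0.8, n_sims=60, seed=52, chain_length=1500,
        )
        # binomial 99% bound at n=60 around 0.8 is ~0.13
        assert abs(cov.fraction - 0.8) < 0.14

    def test_requires_minimum_sims(self):
        cfg = SimulationConfig(m=10, n=4, sigma2=0.25, d2=0.25, r2_er_true=0.5, seed=1)
        with pytest.raises(ValueError, match="n_sims"):
            coverage_experiment(cfg, n_sims=1)
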