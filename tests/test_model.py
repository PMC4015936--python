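import numpy as np
import pytest
from scipy import integrate, stats

from crowdrank.model import (
    LatentState,
    SamplerConfig,
    gibbs_update_latents,
    gibbs_update_locations,
    gibbs_update_precisions,
    initialize_state,
    ranking_probability,
    run_sampler,
    sample_truncated_normal,
)
from crowdrank.rank_io import Ordering

from .conftest import orderings_to_dataset


class TestSamplerConfig:
    def test_defaults_match_standard_schedule(self):
        c = SamplerConfig()
        assert (c.n_chains, c.n_burnin, c.n_retained_per_chain, c.thin) == (4, 10_000, 1_000, 10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_chains": 0},
            {"thin": 0},
            {"n_retained_per_chain": 0},
            {"prior_location_sd": 0.0},
            {"prior_precision_rate": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SamplerConfig(**kwargs)


class TestTruncatedNormal:
    def test_unbounded_interval_matches_normal_moments(self, rng):
        draws = sample_truncated_normal(2.0, 3.0, -np.inf, np.inf, rng, size=100_000)
        assert abs(draws.mean() - 2.0) < 0.02 * 3.0
        assert abs(draws.std() - 3.0) < 0.05 * 3.0

    def test_one_sided_interval_matches_truncnorm(self, rng):
        draws = sample_truncated_normal(0.0, 1.0, 1.0, np.inf, rng, size=100_000)
        ref = stats.truncnorm(1.0, np.inf)
        assert abs(draws.mean() - ref.mean()) < 0.01
        assert abs(draws.var() - ref.var()) < 0.01
        assert draws.min() > 1.0

    def test_two_sided_distribution_matches_truncnorm(self, rng):
        draws = sample_truncated_normal(0.5, 2.0, -1.0, 2.0, rng, size=50_000)
        ref = stats.truncnorm((-1.0 - 0.5) / 2.0, (2.0 - 0.5) / 2.0, loc=0.5, scale=2.0)
        assert stats.kstest(draws, ref.cdf).pvalue > 1e-4

    def test_far_tail_draws_stay_in_interval(self, rng):
        draws = sample_truncated_normal(0.0, 1.0, 8.0, 9.0, rng, size=1_000)
        assert np.all(np.isfinite(draws))
        assert np.all((draws > 8.0) & (draws < 9.0))
        # mass concentrates near the lower edge of a far-tail interval
        assert np.median(draws) < 8.5

    def test_vanishing_interval_returns_midpoint(self, rng):
        lo = 0.3
        hi = np.nextafter(np.nextafter(lo, 1), 1)
        draws = sample_truncated_normal(0.3, 1.0, lo, hi, rng, size=100)
        assert np.all((draws > lo) & (draws < hi))

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError, match="lower"):
            sample_truncated_normal(0, 1, 2.0, 1.0, rng)
        with pytest.raises(ValueError, match="sd"):
            sample_truncated_normal(0, -1, 0.0, 1.0, rng)
        with pytest.raises(ValueError, match="finite"):
            sample_truncated_normal(np.nan, 1, 0.0, 1.0, rng)


class TestGibbsLatents:
    def test_two_items_truncation_forced(self, rng):
        d = orderings_to_dataset([(0, 1)])
        state = initialize_state(d, SamplerConfig(), rng)
        for _ in range(200):
            gibbs_update_latents(state, d, rng)
            assert state.x[0, 0] < state.x[0, 1]

    def test_constraint_preserved_over_sweeps(self, rng):
        d = orderings_to_dataset([(2, 0, 1), (1, 2, 0)])
        om = d.ordering_matrix()
        state = initialize_state(d, SamplerConfig(), rng)
        for _ in range(2_000):
            gibbs_update_latents(state, d, rng)
            state.check_order_constraint(om)

    def test_marginals_match_rejection_sampler(self, rng):
        """With equal locations, long-run latents follow normal order statistics."""
        d = orderings_to_dataset([(0, 1, 2)])
        state = initialize_state(d, SamplerConfig(), rng)
        state.mu = np.zeros(3)
        state.lam = np.ones(1)
        burn, keep, thin = 200, 2_000, 5
        kept = np.empty((keep, 3))
        for _ in range(burn):
            gibbs_update_latents(state, d, rng)
        for t in range(keep):
            for _ in range(thin):
                gibbs_update_latents(state, d, rng)
            kept[t] = state.x[0]
        # rejection oracle: iid normals conditioned on being already sorted
        raw = rng.normal(size=(60_000, 3))
        sorted_rows = raw[np.all(np.diff(raw, axis=1) > 0, axis=1)]
        for pos in range(3):
            p = stats.ks_2samp(kept[:, pos], sorted_rows[:, pos]).pvalue
            assert p > 1e-4, f"order-statistic marginal mismatch at position {pos}"


class TestGibbsLocations:
    def test_full_conditional_matches_quadrature(self, rng):
        """Sampled moments agree with brute-force integration of prior x likelihood."""
        d = orderings_to_dataset([(0, 1, 2), (1, 0, 2)])
        config = SamplerConfig(prior_location_sd=1.3)
        state = initialize_state(d, config, rng)
        state.x = np.array([[0.2, 0.9, 1.7], [-0.4, 0.3, 2.2]])
        state.lam = np.array([1.8, 0.6])
        i = 1

        def unnorm(m):
            prior = stats.norm.pdf(m, 0, config.prior_location_sd)
            lik = np.prod(
                [stats.norm.pdf(state.x[j, i], m, state.lam[j] ** -0.5) for j in range(2)],
                axis=0,
            )
            return prior * lik

        grid = np.linspace(-6, 6, 20_001)
        w = unnorm(grid)
        w /= integrate.trapezoid(w, grid)
        q_mean = integrate.trapezoid(grid * w, grid)
        q_var = integrate.trapezoid((grid - q_mean) ** 2 * w, grid)

        draws = np.empty(20_000)
        x_frozen = state.x.copy()
        for t in range(draws.size):
            state.x = x_frozen.copy()
            gibbs_update_locations(state, d, config, rng)
            draws[t] = state.mu[i]
        assert abs(draws.mean() - q_mean) < 4 * np.sqrt(q_var / draws.size)
        assert abs(draws.var() - q_var) < 0.05 * q_var

    def test_infinite_precision_limit_concentrates(self, rng):
        d = orderings_to_dataset([(0, 1)])
        config = SamplerConfig()
        state = initialize_state(d, config, rng)
        c = 0.7
        state.x = np.full((1, 2), c)
        state.lam = np.array([1e12])
        gibbs_update_locations(state, d, config, rng)
        assert np.allclose(state.mu, c, atol=1e-3)


class TestGibbsPrecisions:
    def test_full_conditional_matches_quadrature(self, rng):
        d = orderings_to_dataset([(0, 1, 2)])
        config = SamplerConfig(prior_precision_shape=2.0, prior_precision_rate=2.0)
        state = initialize_state(d, config, rng)
        state.mu = np.array([0.0, 0.5, 1.5])
        state.x = np.array([[0.3, 0.2, 2.0]])

        resid2 = ((state.x[0] - state.mu) ** 2).sum()
        shape = config.prior_precision_shape + 1.5
        rate = config.prior_precision_rate + 0.5 * resid2

        def unnorm(lam):
            prior = stats.gamma.pdf(lam, config.prior_precision_shape,
                                    scale=1 / config.prior_precision_rate)
            lik = np.prod(
                [stats.norm.pdf(state.x[0, i], state.mu[i], lam ** -0.5) for i in range(3)],
                axis=0,
            )
            return prior * lik

        grid = np.linspace(1e-6, 30, 200_001)
        w = unnorm(grid)
        w /= integrate.trapezoid(w, grid)
        q_mean = integrate.trapezoid(grid * w, grid)
        assert abs(q_mean - shape / rate) < 1e-3  # conjugate form agrees with quadrature

        x_frozen = state.x.copy()
        draws = np.empty(20_000)
        for t in range(draws.size):
            state.x = x_frozen.copy()
            gibbs_update_precisions(state, d, config, rng)
            draws[t] = state.lam[0]
        assert abs(draws.mean() - shape / rate) < 4 * np.sqrt(shape / rate**2 / draws.size)

    def test_zero_residuals_raise_conditional_mean_above_prior(self, rng):
        d = orderings_to_dataset([(0, 1)])
        config = SamplerConfig()
        state = initialize_state(d, config, rng)
        state.mu = np.array([0.0, 1.0])
        state.x = state.mu[None, :].copy()
        draws = []
        for _ in range(3_000):
            state.x = state.mu[None, :].copy()
            gibbs_update_precisions(state, d, config, rng)
            draws.append(state.lam[0])
        prior_mean = config.prior_precision_shape / config.prior_precision_rate
        cond_mean = (config.prior_precision_shape + 1.0) / config.prior_precision_rate
        assert cond_mean > prior_mean
        assert abs(np.mean(draws) - cond_mean) < 0.1


class TestInitializeState:
    def test_unanimity_initial_locations_follow_votes(self, rng):
        d = orderings_to_dataset([(2, 0, 1)] * 5)
        state = initialize_state(d, SamplerConfig(), rng)
        assert list(np.argsort(state.mu)) == [2, 0, 1]

    def test_order_invariant_on_random_datasets(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 8))
            j = int(rng.integers(1, 6))
            d = orderings_to_dataset([rng.permutation(n) for _ in range(j)])
            state = initialize_state(d, SamplerConfig(), rng)
            state.check_order_constraint(d.ordering_matrix())

    def test_seed_changes_x_not_mu(self):
        d = orderings_to_dataset([(0, 1, 2), (2, 1, 0)])
        s1 = initialize_state(d, SamplerConfig(), np.random.default_rng(1))
        s2 = initialize_state(d, SamplerConfig(), np.random.default_rng(2))
        assert np.array_equal(s1.mu, s2.mu)
        assert not np.array_equal(s1.x, s2.x)


FAST = SamplerConfig(n_chains=2, n_burnin=200, n_retained_per_chain=200, thin=1, base_seed=5)


class TestRunSampler:
    def test_unanimous_pair_strongly_ordered(self):
        d = orderings_to_dataset([(0, 1)] * 3)
        post = run_sampler(d, FAST, debug=True)
        p_before = (post.mu[:, 0] < post.mu[:, 1]).mean()
        assert p_before > 0.9

    def test_same_seed_bit_identical(self):
        d = orderings_to_dataset([(1, 0, 2), (0, 2, 1)])
        p1 = run_sampler(d, FAST)
        p2 = run_sampler(d, FAST)
        assert np.array_equal(p1.mu, p2.mu)
        assert np.array_equal(p1.sigma, p2.sigma)
        p3 = run_sampler(d, SamplerConfig(**{**FAST.__dict__, "base_seed": 6}))
        assert not np.array_equal(p1.mu, p3.mu)

    def test_posterior_shape_and_chain_tags(self):
        d = orderings_to_dataset([(1, 0, 2)])
        post = run_sampler(d, FAST)
        assert post.mu.shape == (400, 3)
        assert post.sigma.shape == (400, 1)
        assert np.bincount(post.chain).tolist() == [200, 200]

    def test_rejects_degenerate_inputs(self):
        from crowdrank.rank_io import RankingDataset

        with pytest.raises(ValueError):  # no participants
            RankingDataset(("A", "B"), (), np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError):  # a single item is not rankable
            orderings_to_dataset([(0,)])

    def test_save_load_round_trip(self, tmp_path):
        d = orderings_to_dataset([(1, 0, 2), (2, 1, 0)])
        post = run_sampler(d, FAST)
        post.save(tmp_path / "post")
        from crowdrank.model import Posterior

        back = Posterior.load(tmp_path / "post")
        assert np.allclose(back.mu, post.mu)
        assert np.allclose(back.sigma, post.sigma)
        assert back.item_labels == post.item_labels
        assert back.config == post.config


class TestRankingProbability:
    def test_two_equal_items_symmetric(self, rng):
        p = ranking_probability([0.0, 0.0], 1.0, Ordering((0, 1)), 40_000, rng)
        assert abs(p - 0.5) < 0.01

    def test_three_exchangeable_items_uniform(self, rng):
        p = ranking_probability([1.0, 1.0, 1.0], 2.0, Ordering((2, 0, 1)), 60_000, rng)
        assert abs(p - 1 / 6) < 0.01

    def test_separated_items_near_certain(self, rng):
        p = ranking_probability([0.0, 10.0], 0.1, Ordering((0, 1)), 5_000, rng)
        assert p == 1.0

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            ranking_probability([0.0, 1.0], 0.0, Ordering((0, 1)), 10, rng)
        with pytest.raises(ValueError):
            ranking_probability([0.0, 1.0, 2.0], 1.0, Ordering((0, 1)), 10, rng)
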