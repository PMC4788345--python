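"""Sampler correctness: kernel, Gibbs updates, Metropolis, diagnostics."""

import numpy as np
import pytest
import scipy.stats

from ancfreq.datatypes import LocusMap, RunConfig
from ancfreq.discriminant import LikelihoodGrid
from ancfreq.errors import AncfreqError
from ancfreq.mcmc import (
    KernelCache,
    _beta_logpdf_sum,
    ess,
    gibbs_update_q,
    gibbs_update_z,
    kernel_weight,
    metropolis_update_sigma,
    posterior_shapes,
    psrf,
    run_mcmc,
    summarize_posterior,
)


def _map(n, chrom="1"):
    return LocusMap(
        chrom=np.array([chrom] * n, dtype=object), pos=np.arange(1, n + 1) * 10
    )


POINT_MASS_SIGMA = 0.01  # below this scale the truncated kernel keeps only x


class TestKernel:
    def test_zero_distance_weight_is_one(self):
        assert kernel_weight(7, 7, 0.5) == 1.0

    def test_large_sigma_limit(self):
        assert kernel_weight(0, 50, 1e12) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert kernel_weight(10, 12, 4.0) == pytest.approx(np.exp(-1.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(AncfreqError):
            kernel_weight(0, 1, 0.0)

    def test_cache_is_symmetric_and_self_weighted(self):
        cache = KernelCache.build(sigma=25.0, epsilon=1e-6)
        sl = slice(0, 100)
        n50 = dict(cache.neighbors(50, sl))
        assert n50[50] == 1.0
        for i, wgt in cache.neighbors(50, sl):
            assert (50, pytest.approx(wgt)) in [
                (j, pytest.approx(v)) for j, v in cache.neighbors(i, sl) if j == 50
            ]
        assert all(0 < wgt <= 1 for wgt in n50.values())

    def test_truncation_halfwidth(self):
        cache = KernelCache.build(sigma=POINT_MASS_SIGMA, epsilon=1e-6)
        assert cache.halfwidth == 0  # point mass at the focal locus


class TestGibbsQ:
    def test_point_mass_kernel_gives_closed_form_beta(self):
        """With a point-mass kernel the conditional is Beta(z+1, 2n-z+1)."""
        lm = _map(1)
        cache = KernelCache.build(POINT_MASS_SIGMA, 1e-6)
        slices = list(lm.chrom_slices().values())
        rng = np.random.default_rng(0)
        z_tot = np.array([10.0])
        draws = np.array(
            [
                gibbs_update_q(z_tot, 50.0, cache, slices, 1.0, 1.0, rng)[0][0]
                for _ in range(4000)
            ]
        )
        assert draws.mean() == pytest.approx(11 / 52, abs=0.005)
        ks = scipy.stats.kstest(draws, scipy.stats.beta(11, 41).cdf)
        assert ks.pvalue > 0.01

    def test_all_zero_counts_push_q_to_zero(self):
        lm = _map(5)
        cache = KernelCache.build(100.0, 1e-6)
        slices = list(lm.chrom_slices().values())
        rng = np.random.default_rng(1)
        q, alpha, beta = gibbs_update_q(
            np.zeros(5), 100.0, cache, slices, 1.0, 1.0, rng
        )
        assert np.all(alpha == 1.0)
        assert np.all(beta > 100.0)
        assert np.all(q < 0.1)

    def test_large_sigma_homogenizes_adjacent_shapes(self):
        """Two adjacent loci with opposite counts share nearly equal shapes."""
        lm = _map(2)
        slices = list(lm.chrom_slices().values())
        z_tot = np.array([40.0, 10.0])
        a_small, b_small = posterior_shapes(
            z_tot, 50.0, KernelCache.build(POINT_MASS_SIGMA, 1e-6), slices, 1, 1
        )
        np.testing.assert_allclose(a_small, [41.0, 11.0])
        a_big, b_big = posterior_shapes(
            z_tot, 50.0, KernelCache.build(1e6, 1e-6), slices, 1, 1
        )
        # hand-summed weighted counts: both loci see ~(40 + 10) successes
        np.testing.assert_allclose(a_big, [51.0, 51.0], rtol=1e-4)
        np.testing.assert_allclose(b_big, [51.0, 51.0], rtol=1e-4)


class TestGibbsZ:
    def test_equal_likelihoods_recover_binomial_prior(self):
        like = np.ones((1, 20000, 3))
        rng = np.random.default_rng(2)
        z = gibbs_update_z(like, np.array([0.5]), rng)
        freqs = np.bincount(z.ravel(), minlength=3) / z.size
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_degenerate_prior_forces_state(self):
        like = np.ones((1, 500, 3))
        rng = np.random.default_rng(3)
        z = gibbs_update_z(like, np.array([1.0]), rng)
        assert np.all(z == 2)
        z = gibbs_update_z(like, np.array([0.0]), rng)
        assert np.all(z == 0)

    def test_matches_enumerated_categorical_chi2(self):
        """Random (likelihood, q) cases against brute-force enumeration."""
        from helpers import z_gibbs_chi2_failures

        assert z_gibbs_chi2_failures(n_cases=200, n_draws=10_000, seed=4) <= 1

    def test_z_values_stay_in_state_space(self):
        rng = np.random.default_rng(5)
        like = rng.uniform(0.1, 1.0, size=(50, 7, 3))
        z = gibbs_update_z(like, rng.uniform(0, 1, size=50), rng)
        assert set(np.unique(z)).issubset({0, 1, 2})


class _StubRng:
    """Deterministic stand-in for the proposal and accept draws."""

    def __init__(self, normal, uniform=0.5):
        self._normal = normal
        self._uniform = uniform

    def standard_normal(self):
        return self._normal

    def random(self):
        return self._uniform


class TestMetropolisSigma:
    def _setup(self, n=3, sigma=10.0, seed=6):
        lm = _map(n)
        slices = list(lm.chrom_slices().values())
        rng = np.random.default_rng(seed)
        z_tot = rng.integers(0, 100, size=n).astype(float)
        cache = KernelCache.build(sigma, 1e-6)
        q, a, b = gibbs_update_q(z_tot, 100.0, cache, slices, 1.0, 1.0, rng)
        return lm, slices, z_tot, q, (a, b)

    def test_identity_proposal_always_accepted(self):
        lm, slices, z_tot, q, shapes = self._setup()
        cfg = RunConfig()
        new, ok = metropolis_update_sigma(
            q, z_tot, 100.0, 10.0, cfg, _StubRng(0.0, uniform=0.999999), slices,
            current_shapes=shapes,
        )
        assert ok and new == pytest.approx(10.0)

    def test_out_of_bounds_proposal_rejected(self):
        lm, slices, z_tot, q, shapes = self._setup()
        cfg = RunConfig(sigma_min=1.0, sigma_max=100.0)
        new, ok = metropolis_update_sigma(
            q, z_tot, 100.0, 90.0, cfg, _StubRng(5.0), slices,
            current_shapes=shapes,
        )
        assert not ok and new == 90.0

    def test_log_ratio_matches_beta_logpdf_oracle(self):
        """Acceptance uses the summed log-beta-density difference (+Jacobian)."""
        lm, slices, z_tot, q, shapes = self._setup()
        cfg = RunConfig(sigma_step=0.3)
        sigma, step_draw = 10.0, 0.7
        proposal = sigma * np.exp(cfg.sigma_step * step_draw)
        prop_shapes = posterior_shapes(
            z_tot, 100.0, KernelCache.build(proposal, cfg.epsilon), slices, 1, 1
        )
        want = (
            np.sum(scipy.stats.beta.logpdf(q, *prop_shapes))
            - np.sum(scipy.stats.beta.logpdf(q, *shapes))
            + np.log(proposal / sigma)
        )
        ours = (
            _beta_logpdf_sum(q, *prop_shapes)
            - _beta_logpdf_sum(q, *shapes)
            + np.log(proposal / sigma)
        )
        assert ours == pytest.approx(want, abs=1e-10)
        # accept/reject decision consistent with the oracle ratio
        threshold = np.exp(min(want, 0.0))
        new, ok = metropolis_update_sigma(
            q, z_tot, 100.0, sigma, cfg,
            _StubRng(step_draw, uniform=threshold * 0.5), slices,
            current_shapes=shapes,
        )
        assert ok and new == pytest.approx(proposal)

    def test_fixed_state_recovers_uniform_prior(self):
        """With z fixed, alternating q-draws and sigma-updates must leave the
        sigma marginal equal to its uniform prior (the beta conditionals
        integrate to one for every sigma)."""
        lm = _map(40)
        slices = list(lm.chrom_slices().values())
        rng = np.random.default_rng(7)
        z_tot = rng.integers(10, 90, size=40).astype(float)
        cfg = RunConfig(sigma_min=1.0, sigma_max=21.0, sigma_step=0.6)
        sigma = 11.0
        draws = []
        for _ in range(6000):
            cache = KernelCache.build(sigma, cfg.epsilon)
            q, a, b = gibbs_update_q(z_tot, 100.0, cache, slices, 1, 1, rng)
            sigma, _ = metropolis_update_sigma(
                q, z_tot, 100.0, sigma, cfg, rng, slices, current_shapes=(a, b)
            )
            draws.append(sigma)
        sub = np.array(draws[1000::10])
        ks = scipy.stats.kstest(
            sub, scipy.stats.uniform(1.0, 20.0).cdf
        )
        assert abs(sub.mean() - 11.0) < 1.2
        assert ks.pvalue > 1e-3


def _flat_grid(n_loci, n_ind):
    return LikelihoodGrid(
        likelihoods=np.ones((n_loci, n_ind, 3)),
        scores=np.zeros((n_loci, n_ind)),
    )


def _forced_grid(n_loci, n_ind, state=2):
    like = np.full((n_loci, n_ind, 3), 1e-8)
    like[:, :, state] = 10.0
    return LikelihoodGrid(likelihoods=like, scores=np.zeros((n_loci, n_ind)))


class TestRunMcmc:
    def test_forced_grid_recovers_q_near_one(self):
        lm = _map(30)
        cfg = RunConfig(chains=1, iters=400, burnin=100, thin=2, seed=0)
        chains = run_mcmc(_forced_grid(30, 20), lm, cfg)
        s = summarize_posterior(chains, cfg, two_n=40.0)
        assert np.all(s.q_mean > 0.9)

    def test_flat_grid_prior_only_limit(self):
        """No genetic signal: q hovers near 1/2 and chains agree (PSRF ~ 1)."""
        lm = _map(30)
        cfg = RunConfig(
            chains=2, iters=800, burnin=200, thin=2, seed=1,
            sigma_min=1.0, sigma_max=50.0,
        )
        chains = run_mcmc(_flat_grid(30, 20), lm, cfg)
        s = summarize_posterior(chains, cfg, two_n=40.0)
        assert abs(s.q_mean.mean() - 0.5) < 0.1
        assert np.median(s.psrf_q) < 1.2

    def test_state_invariants_hold_throughout(self):
        lm = _map(25)
        cfg = RunConfig(chains=2, iters=300, burnin=50, thin=1, seed=2)
        chains = run_mcmc(_flat_grid(25, 10), lm, cfg)
        for c in chains:
            assert np.all((c.q >= 0) & (c.q <= 1))
            assert np.all((c.z_tot >= 0) & (c.z_tot <= 20))
            assert np.all(
                (c.sigma >= cfg.sigma_min) & (c.sigma <= cfg.sigma_max)
            )

    def test_seeded_determinism(self):
        lm = _map(20)
        cfg = RunConfig(chains=2, iters=200, burnin=50, thin=2, seed=3)
        rng_grid = np.random.default_rng(8)
        like = rng_grid.uniform(0.1, 1.0, size=(20, 10, 3))
        grid = LikelihoodGrid(likelihoods=like, scores=np.zeros((20, 10)))
        a = run_mcmc(grid, lm, cfg)
        b = run_mcmc(grid, lm, cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.q, cb.q)
            np.testing.assert_array_equal(ca.sigma, cb.sigma)

    def test_point_mass_kernel_matches_independent_beta_posterior(self):
        """sigma -> 0 limit: the process posterior collapses to the
        independent beta-binomial posterior at each locus (fixed z)."""
        from helpers import sigma_zero_limit_pvalue

        assert sigma_zero_limit_pvalue(seed=4) > 0.01

    def test_monotone_smoothing_shrinks_q_variance(self):
        """Larger sigma never increases the spread of posterior-mean q."""
        lm = _map(80)
        rng = np.random.default_rng(9)
        z_tot = rng.integers(0, 60, size=80).astype(float)
        slices = list(lm.chrom_slices().values())
        spreads = []
        for sigma in (0.01, 1.0, 10.0, 100.0, 1000.0):
            a, b = posterior_shapes(
                z_tot, 60.0, KernelCache.build(sigma, 1e-6), slices, 1, 1
            )
            spreads.append(np.var(a / (a + b)))
        assert all(s2 <= s1 + 1e-12 for s1, s2 in zip(spreads, spreads[1:]))


class TestDiagnostics:
    def test_identical_chains_have_unit_psrf(self):
        # identical chains: B = 0, so the statistic is sqrt((n-1)/n) ~ 1
        chain = np.random.default_rng(10).normal(size=500)
        assert psrf(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.005)

    def test_disjoint_chains_have_large_psrf(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.1, size=500)
        b = rng.normal(10, 0.1, size=500)
        assert psrf(np.stack([a, b])) > 10

    def test_zero_variance_chains_defined_as_one(self):
        flat = np.ones((2, 100))
        assert psrf(flat) == 1.0

    def test_iid_chain_ess_near_n(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=4000)
        assert ess(x) == pytest.approx(4000, rel=0.15)

    def test_autocorrelated_chain_ess_shrinks(self):
        rng = np.random.default_rng(13)
        x = np.empty(4000)
        x[0] = 0.0
        for i in range(1, 4000):
            x[i] = 0.9 * x[i - 1] + rng.normal()
        # AR(1) with rho=0.9 -> ESS ~ n * (1-rho)/(1+rho) ~ n/19
        assert ess(x) < 1000

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(14)
        chains = np.empty((2, 2000))
        chains[:, 0] = 0.0
        for i in range(1, 2000):
            chains[:, i] = 0.5 * chains[:, i - 1] + rng.normal(size=2)
        ours = sum(ess(chains[c]) for c in range(2))
        theirs = float(az.ess(az.convert_to_dataset(chains[:, :, None]))["x"].values[0])
        assert ours == pytest.approx(theirs, rel=0.25)
        r_ours = psrf(chains)
        r_theirs = float(
            az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values[0]
        )
        assert r_ours == pytest.approx(r_theirs, abs=0.05)


class TestSummaries:
    def _chains(self, q_draws, z_draws, sigma=None):
        from ancfreq.mcmc import ChainDraws

        n, L = q_draws.shape
        return [
            ChainDraws(
                q=q_draws,
                z_tot=z_draws,
                sigma=sigma if sigma is not None else np.ones(n),
                dosage_sum=np.tile(z_draws.sum(axis=0) / 10, (1, 1)).T / n,
                n_retained=n,
                accept_sigma=0.3,
            )
        ]

    def test_degenerate_draws_collapse_summaries(self):
        q = np.full((50, 3), 0.3)
        z = np.full((50, 3), 12, dtype=np.int32)
        cfg = RunConfig(bb_intervals=False)
        s = summarize_posterior(self._chains(q, z), cfg, two_n=40.0)
        for field in (s.q_mean, s.q_median, s.q_low, s.q_high):
            np.testing.assert_allclose(field, 0.3)

    def test_bb_interval_matches_beta_quantile_oracle(self):
        """Fixed z_x=20 of 2n=50 copies -> equal-tail Beta(21, 31) interval."""
        n_draws = 6000
        q = np.full((n_draws, 1), 0.4)
        z = np.full((n_draws, 1), 20, dtype=np.int32)
        cfg = RunConfig(seed=5)
        s = summarize_posterior(
            self._chains(q, z), cfg, two_n=50.0,
            rng=np.random.default_rng(15),
        )
        lo, hi = scipy.stats.beta(21, 31).ppf([0.025, 0.975])
        assert s.bb_low[0] == pytest.approx(lo, abs=0.02)
        assert s.bb_high[0] == pytest.approx(hi, abs=0.02)

    def test_bb_interval_at_least_as_wide_under_heavy_smoothing(self):
        """Kernel pooling narrows the process posterior; the beta-binomial
        fallback keeps the per-locus sampling uncertainty."""
        lm = _map(60)
        rng = np.random.default_rng(16)
        like = np.full((60, 25, 3), 1e-12)
        states = rng.integers(0, 3, size=(60, 25))
        for x in range(60):
            like[x, np.arange(25), states[x]] = 1.0
        grid = LikelihoodGrid(likelihoods=like, scores=np.zeros((60, 25)))
        cfg = RunConfig(
            chains=1, iters=1500, burnin=500, thin=2,
            sigma_min=400.0, sigma_max=500.0, seed=6,
        )
        chains = run_mcmc(grid, lm, cfg)
        s = summarize_posterior(chains, cfg, two_n=50.0)
        ccbpm_width = s.q_high - s.q_low
        bb_width = s.bb_high - s.bb_low
        assert np.mean(bb_width >= ccbpm_width) > 0.95
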