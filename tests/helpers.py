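"""Shared independent oracles used by both module and acceptance tests."""

import numpy as np
import scipy.stats

from ancfreq.datatypes import LocusMap, RunConfig
from ancfreq.discriminant import LikelihoodGrid, Window, fit_discriminant
from ancfreq.mcmc import gibbs_update_z, run_mcmc


def z_gibbs_chi2_failures(n_cases: int, n_draws: int, seed: int) -> int:
    """Compare the z Gibbs sampler against brute-force enumeration.

    For random (likelihood, q) pairs the categorical probabilities are
    enumerated exactly; draw frequencies are chi-square tested against them.
    Returns the number of cases with p < 1e-4.
    """
    rng = np.random.default_rng(seed)
    fails = 0
    chunk = 100
    for start in range(0, n_cases, chunk):
        m = min(chunk, n_cases - start)
        like = rng.uniform(0.05, 3.0, size=(m, 1, 3))
        q = rng.uniform(0.02, 0.98, size=m)
        prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1)
        expect = like[:, 0, :] * prior
        expect /= expect.sum(axis=1, keepdims=True)
        tiled = np.repeat(like, n_draws, axis=1)
        z = gibbs_update_z(tiled, q, rng)
        for c in range(m):
            obs = np.bincount(z[c], minlength=3)
            p = scipy.stats.chisquare(obs, expect[c] * n_draws).pvalue
            fails += p < 1e-4
    return int(fails)


def da_oracle_max_deviation(n_windows: int, seed: int) -> float:
    """Max deviation of fitted discriminant axes from a dense generalized-
    eigenproblem solve (explicit inverse + nonsymmetric eig) over random
    windows; axes are compared up to scale and sign."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_windows):
        p = int(rng.integers(2, 7))
        base = rng.normal(size=p)
        groups = tuple(
            g * base + rng.normal(scale=0.8, size=(int(rng.integers(10, 40)), p))
            for g in range(3)
        )
        win = Window(focal=0, members=np.arange(p))
        model = fit_discriminant(win, groups, ridge=1e-6)
        n_tot = sum(g.shape[0] for g in groups)
        mu = np.vstack(groups).mean(axis=0)
        s_w = sum(
            (g - g.mean(axis=0)).T @ (g - g.mean(axis=0)) for g in groups
        ) / (n_tot - 3)
        s_w[np.diag_indices_from(s_w)] += 1e-6 * np.mean(np.diag(s_w))
        dev = np.stack([g.mean(axis=0) - mu for g in groups])
        s_b = dev.T @ dev / 3.0
        vals, vecs = np.linalg.eig(np.linalg.inv(s_w) @ s_b)
        lead = np.real(vecs[:, np.argmax(np.real(vals))])
        got = model.coefficients / np.linalg.norm(model.coefficients)
        want = lead / np.linalg.norm(lead)
        if np.dot(got, want) < 0:
            want = -want
        worst = max(worst, float(np.max(np.abs(got - want))))
    return worst


def sigma_zero_limit_pvalue(seed: int) -> float:
    """KS p-value comparing point-mass-kernel q draws (fixed z) against the
    independent beta-binomial posterior Beta(z + 1, 2n - z + 1)."""
    lm = LocusMap(
        chrom=np.array(["1"] * 6, dtype=object), pos=np.arange(1, 7) * 10
    )
    like = np.full((6, 20, 3), 1e-12)
    like[:, :12, 2] = 1.0
    like[:, 12:, 0] = 1.0
    grid = LikelihoodGrid(likelihoods=like, scores=np.zeros((6, 20)))
    cfg = RunConfig(
        chains=1, iters=4000, burnin=500, thin=1,
        sigma_min=0.001, sigma_max=0.01, seed=seed,
    )
    chains = run_mcmc(grid, lm, cfg)
    draws = chains[0].q[:, 2]
    return float(scipy.stats.kstest(draws, scipy.stats.beta(25, 17).cdf).pvalue)
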