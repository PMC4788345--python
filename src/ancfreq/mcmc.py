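"""Continuous correlated beta process sampler for ancestry frequencies.

The latent state is (q, z, sigma): per-locus source-A ancestry frequencies
``q_x`` in [0, 1], per-locus per-admixed-individual ancestry dosages
``z_xj`` in {0, 1, 2}, and the squared-exponential kernel scale ``sigma``.

One MCMC sweep performs, in order: a Gibbs update of every ``z_xj`` from the
categorical proportional to (score likelihood) x Binomial(2, q_x) prior; a
Gibbs update of every ``q_x`` from the kernel-weighted beta conditional

    q_x ~ Beta(alpha0 + sum_i z_i k(x, i),  beta0 + sum_i (2 n_i - z_i) k(x, i))

with ``k(x, i) = exp(-(x - i)^2 / sigma)`` and marker-index distance confined
to one chromosome; and a log-scale random-walk Metropolis update of ``sigma``
targeting the product of those beta conditionals (the only term of the
generalized posterior in which sigma appears) under a uniform prior on
``[sigma_min, sigma_max]``.

Because information is pooled across linked loci, the process-model posterior
for ``q_x`` is narrower than the data alone support; a beta-binomial interval
fallback built from the raw latent counts is therefore offered alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from ancfreq.datatypes import LocusMap, PosteriorSummary, RunConfig
from ancfreq.discriminant import LikelihoodGrid
from ancfreq.errors import AncfreqError, NumericalError

log = logging.getLogger(__name__)

_Q_EPS = 1e-12  # clip q away from {0, 1} inside log-density evaluations


def kernel_weight(x, i, sigma: float):
    """Squared-exponential kernel ``exp(-(x - i)^2 / sigma)``.

    ``x`` and ``i`` are marker indices on the same chromosome (weights across
    chromosomes are defined as zero and handled by the caller).
    """
    if sigma <= 0:
        raise AncfreqError("kernel scale sigma must be positive")
    d = np.asarray(x, dtype=float) - np.asarray(i, dtype=float)
    return np.exp(-(d * d) / sigma)


@dataclass
class KernelCache:
    """Truncated symmetric kernel stencil for equally indexed loci.

    Neighbors farther than ``halfwidth`` markers have weight below the
    truncation tolerance ``epsilon`` and are dropped.  ``taps`` holds the full
    symmetric stencil of length ``2 * halfwidth + 1`` with the self-weight
    ``k(x, x) = 1`` in the middle; truncation is symmetric by construction,
    so (x, i) is cached iff (i, x) is.
    """

    sigma: float
    epsilon: float
    halfwidth: int
    taps: np.ndarray

    @classmethod
    def build(cls, sigma: float, epsilon: float) -> "KernelCache":
        if sigma <= 0:
            raise AncfreqError("kernel scale sigma must be positive")
        h = int(math.floor(math.sqrt(-sigma * math.log(epsilon))))
        offsets = np.arange(-h, h + 1, dtype=float)
        taps = np.exp(-(offsets**2) / sigma)
        taps[np.abs(offsets) > 0] *= taps[np.abs(offsets) > 0] >= epsilon
        return cls(sigma=sigma, epsilon=epsilon, halfwidth=h, taps=taps)

    def neighbors(self, x: int, chrom_slice: slice) -> list[tuple[int, float]]:
        """(neighbor index, weight) pairs for locus ``x`` within its chromosome."""
        out = []
        for off in range(-self.halfwidth, self.halfwidth + 1):
            i = x + off
            w = self.taps[off + self.halfwidth]
            if chrom_slice.start <= i < chrom_slice.stop and w > 0:
                out.append((i, float(w)))
        return out


def _smoothed(v: np.ndarray, cache: KernelCache, slices: list[slice]) -> np.ndarray:
    """Per-chromosome kernel-weighted sums ``sum_i v_i k(x, i)``."""
    out = np.empty_like(v, dtype=float)
    h = cache.halfwidth
    for sl in slices:
        seg = v[sl]
        # centered convolution that also handles stencils wider than the
        # chromosome (np.convolve "same" keys its length to the longer input)
        full = np.convolve(seg, cache.taps)
        out[sl] = full[h : h + len(seg)]
    return out


def posterior_shapes(
    z_tot: np.ndarray,
    two_n: float | np.ndarray,
    cache: KernelCache,
    slices: list[slice],
    alpha0: float,
    beta0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-weighted beta shape parameters for every locus."""
    alpha = alpha0 + _smoothed(np.asarray(z_tot, dtype=float), cache, slices)
    rest = np.asarray(two_n, dtype=float) - z_tot
    beta = beta0 + _smoothed(rest, cache, slices)
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
        raise NumericalError("non-finite beta shape parameters")
    return alpha, beta


def gibbs_update_q(
    z_tot: np.ndarray,
    two_n: float | np.ndarray,
    cache: KernelCache,
    slices: list[slice],
    alpha0: float,
    beta0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw q for every locus; returns (q, alpha, beta)."""
    alpha, beta = posterior_shapes(z_tot, two_n, cache, slices, alpha0, beta0)
    return rng.beta(alpha, beta), alpha, beta


def gibbs_update_z(
    likelihoods: np.ndarray, q: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw z_xj from the categorical with mass prop. to likelihood x prior.

    ``likelihoods`` is the (L, n, 3) score-likelihood grid (or an (n, 3)
    slice); the Binomial(2, q_x) prior supplies the state weights
    ``((1-q)^2, 2 q (1-q), q^2)``.
    """
    like = np.asarray(likelihoods, dtype=float)
    squeeze = like.ndim == 2
    if squeeze:
        like = like[None, :, :]
        q = np.atleast_1d(np.asarray(q, dtype=float))
    one_m = 1.0 - q
    p0 = like[:, :, 0] * (one_m * one_m)[:, None]
    p1 = like[:, :, 1] * (2.0 * q * one_m)[:, None]
    p2 = like[:, :, 2] * (q * q)[:, None]
    c1 = p0 + p1
    tot = c1 + p2
    bad = tot <= 0.0
    if bad.any():  # total underflow: floor the three masses and renormalize
        log.warning("z-update underflow at %d cells; flooring", int(bad.sum()))
        p0 = np.where(bad, np.maximum(p0, 1e-300), p0)
        c1 = np.where(bad, p0 + np.maximum(p1, 1e-300), c1)
        tot = np.where(bad, c1 + np.maximum(p2, 1e-300), tot)
    u = rng.random(tot.shape) * tot
    z = (u > p0).view(np.int8) + (u > c1).view(np.int8)
    return z[0] if squeeze else z


def _beta_logpdf_sum(q: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> float:
    qc = np.clip(q, _Q_EPS, 1.0 - _Q_EPS)
    return float(
        np.sum(
            (alpha - 1.0) * np.log(qc)
            + (beta - 1.0) * np.log1p(-qc)
            - betaln(alpha, beta)
        )
    )


def metropolis_update_sigma(
    q: np.ndarray,
    z_tot: np.ndarray,
    two_n: float | np.ndarray,
    sigma: float,
    config: RunConfig,
    rng: np.random.Generator,
    slices: list[slice],
    current_shapes: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, bool]:
    """Log-scale random-walk Metropolis update for the kernel scale.

    The acceptance ratio is the product over loci of the beta conditional
    densities of the current q under the proposed versus current shapes,
    times the proposal Jacobian ``sigma' / sigma`` (the random walk is
    symmetric in log sigma while the prior is uniform in sigma itself);
    proposals outside the uniform prior's support are rejected outright.
    """
    proposal = sigma * math.exp(config.sigma_step * rng.standard_normal())
    if not (config.sigma_min <= proposal <= config.sigma_max):
        return sigma, False
    if current_shapes is None:
        cache = KernelCache.build(sigma, config.epsilon)
        current_shapes = posterior_shapes(
            z_tot, two_n, cache, slices, config.alpha0, config.beta0
        )
    prop_cache = KernelCache.build(proposal, config.epsilon)
    prop_shapes = posterior_shapes(
        z_tot, two_n, prop_cache, slices, config.alpha0, config.beta0
    )
    log_ratio = (
        _beta_logpdf_sum(q, *prop_shapes)
        - _beta_logpdf_sum(q, *current_shapes)
        + math.log(proposal / sigma)
    )
    if math.log(rng.random()) < log_ratio:
        return proposal, True
    return sigma, False


@dataclass
class ChainDraws:
    """Thinned post-burn-in draws from one chain."""

    q: np.ndarray  # (R, L)
    z_tot: np.ndarray  # (R, L) latent source-A gene-copy counts
    sigma: np.ndarray  # (R,)
    dosage_sum: np.ndarray  # (L, n) summed z_xj over retained draws
    n_retained: int
    accept_sigma: float


def run_mcmc(
    grid: LikelihoodGrid,
    locus_map: LocusMap,
    config: RunConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> list[ChainDraws]:
    """Run the Gibbs-within-Metropolis sampler; one ChainDraws per chain.

    Each chain initializes z at the per-cell maximum-likelihood state of the
    grid, q at the implied sample frequency, and sigma at the midpoint of
    its uniform prior; the sweep order is all z, kernel rebuild if sigma
    changed, all q, then sigma.
    """
    config.validate()
    like = grid.likelihoods
    n_loci, n_ind, _ = like.shape
    if n_loci != len(locus_map):
        raise AncfreqError("likelihood grid and locus map disagree on loci")
    slices = list(locus_map.chrom_slices().values())
    two_n = 2.0 * n_ind
    if seed is None:
        seed = config.seed
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_seeds = root.spawn(config.chains)
    n_retained = (config.iters - config.burnin + config.thin - 1) // config.thin
    chains: list[ChainDraws] = []
    z_init = np.argmax(like, axis=2).astype(np.int8)
    for ss in chain_seeds:
        rng = np.random.default_rng(ss)
        z = z_init.copy()
        z_tot = z.sum(axis=1, dtype=np.int64)
        q = np.clip(z_tot / two_n, _Q_EPS, 1.0 - _Q_EPS)
        # arithmetic midpoint = mass center of the uniform-in-sigma prior;
        # the log random walk mixes too slowly to recover from a start in
        # the far low tail within practical run lengths
        sigma = 0.5 * (config.sigma_min + config.sigma_max)
        cache = KernelCache.build(sigma, config.epsilon)
        q_draws = np.empty((n_retained, n_loci))
        zt_draws = np.empty((n_retained, n_loci), dtype=np.int32)
        s_draws = np.empty(n_retained)
        dosage_sum = np.zeros((n_loci, n_ind))
        kept = 0
        accepted = 0
        for it in range(config.iters):
            z = gibbs_update_z(like, q, rng)
            z_tot = z.sum(axis=1, dtype=np.int64)
            if cache.sigma != sigma:
                cache = KernelCache.build(sigma, config.epsilon)
            q, alpha, beta = gibbs_update_q(
                z_tot, two_n, cache, slices, config.alpha0, config.beta0, rng
            )
            sigma, ok = metropolis_update_sigma(
                q,
                z_tot,
                two_n,
                sigma,
                config,
                rng,
                slices,
                current_shapes=(alpha, beta),
            )
            accepted += ok
            if not np.all(np.isfinite(q)):
                raise NumericalError(f"non-finite q state at iteration {it}")
            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                q_draws[kept] = q
                zt_draws[kept] = z_tot
                s_draws[kept] = sigma
                dosage_sum += z
                kept += 1
        chains.append(
            ChainDraws(
                q=q_draws[:kept],
                z_tot=zt_draws[:kept],
                sigma=s_draws[:kept],
                dosage_sum=dosage_sum,
                n_retained=kept,
                accept_sigma=accepted / config.iters,
            )
        )
        log.info(
            "chain finished: %d retained draws, sigma acceptance %.3f",
            kept,
            accepted / config.iters,
        )
    return chains


def psrf(chain_draws: np.ndarray) -> np.ndarray | float:
    """Gelman-Rubin potential scale reduction factor.

    ``chain_draws`` has shape (chains, draws) or (chains, draws, ...); at
    least two chains are required.  Parameters with zero total variance are
    reported as exactly 1.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim < 2 or x.shape[0] < 2:
        raise AncfreqError("PSRF needs >= 2 chains of draws")
    m, n = x.shape[0], x.shape[1]
    within = x.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = x.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * within + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / within)
    r = np.where(within <= 0, 1.0, r)
    return float(r) if np.ndim(r) == 0 else r


def ess(draws: np.ndarray) -> np.ndarray | float:
    """Effective sample size via the initial-positive-sequence estimator.

    Autocorrelations are summed in consecutive pairs until the first pair sum
    turns negative (Geyer's initial positive sequence).  ``draws`` has shape
    (n,) or (n, ...); chains with zero variance are reported at full size.
    """
    x = np.asarray(draws, dtype=float)
    scalar = x.ndim == 1
    if scalar:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise AncfreqError("ESS needs at least 2 draws")
    xc = x - x.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:n].real / n
    var0 = acov[0].copy()
    zero = var0 <= 0
    var0[zero] = 1.0
    rho = acov / var0
    # pair sums P_k = rho_{2k} + rho_{2k+1}
    n_pairs = n // 2
    pairs = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    keep = np.logical_and.accumulate(pairs > 0, axis=0)
    tau = 2.0 * np.sum(pairs * keep, axis=0) - 1.0
    tau = np.maximum(tau, 1.0 / n)
    out = n / tau
    out = np.where(zero, float(n), out)
    return float(out[0]) if scalar else out


def summarize_posterior(
    chains: list[ChainDraws],
    config: RunConfig,
    two_n: float,
    rng: np.random.Generator | None = None,
) -> PosteriorSummary:
    """Pool chains into per-locus posterior summaries.

    The 95% equal-tail interval comes from the pooled process-model q draws;
    the beta-binomial fallback draws, for every retained z state, one value
    from ``Beta(z_x + alpha0, 2 n_x - z_x + beta0)`` and takes the same
    equal-tail quantiles, which resists the narrowing caused by kernel
    information pooling.
    """
    if not chains or any(c.n_retained < 2 for c in chains):
        raise AncfreqError("need >= 1 chain with >= 2 retained draws")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    q_all = np.concatenate([c.q for c in chains], axis=0)
    q_mean = q_all.mean(axis=0)
    q_median = np.median(q_all, axis=0)
    q_low, q_high = np.quantile(q_all, [0.025, 0.975], axis=0)
    bb_low = bb_high = None
    if config.bb_intervals:
        zt_all = np.concatenate([c.z_tot for c in chains], axis=0)
        bb = rng.beta(zt_all + config.alpha0, two_n - zt_all + config.beta0)
        bb_low, bb_high = np.quantile(bb, [0.025, 0.975], axis=0)
    total = sum(c.n_retained for c in chains)
    dosage_mean = sum(c.dosage_sum for c in chains) / total
    sigma_draws = np.stack([c.sigma for c in chains])
    if len(chains) >= 2:
        psrf_q = psrf(np.stack([c.q for c in chains]))
        psrf_sigma = float(psrf(sigma_draws))
    else:
        psrf_q = None
        psrf_sigma = None
    ess_q = np.sum([ess(c.q) for c in chains], axis=0)
    ess_sigma = float(np.sum([ess(c.sigma) for c in chains]))
    return PosteriorSummary(
        q_mean=q_mean,
        q_median=q_median,
        q_low=q_low,
        q_high=q_high,
        bb_low=bb_low,
        bb_high=bb_high,
        dosage_mean=dosage_mean,
        sigma_draws=sigma_draws,
        psrf_q=psrf_q,
        ess_q=ess_q,
        psrf_sigma=psrf_sigma,
        ess_sigma=ess_sigma,
        accept_sigma=float(np.mean([c.accept_sigma for c in chains])),
    )
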