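"""End-to-end estimation: discriminant analysis + CCBPM sampling + summary."""

from __future__ import annotations

import logging

import numpy as np

from ancfreq.datatypes import (
    PANEL_ADMIXED,
    PANEL_SOURCE_A,
    PANEL_SOURCE_B,
    GenotypeMatrix,
    LocusMap,
    PosteriorSummary,
    RunConfig,
)
from ancfreq.discriminant import build_reference_models, likelihood_grid
from ancfreq.errors import FormatError
from ancfreq.mcmc import run_mcmc, summarize_posterior

log = logging.getLogger(__name__)


def estimate_ancestry(
    genotypes: GenotypeMatrix,
    locus_map: LocusMap,
    config: RunConfig | None = None,
) -> PosteriorSummary:
    """Estimate per-locus source-A ancestry frequencies in the admixed panel.

    Missing genotypes are mean-imputed per locus within each panel before the
    discriminant analysis.  All randomness (synthetic heterozygote references,
    MCMC, interval fallback draws) derives from ``config.seed``.
    """
    config = config or RunConfig()
    config.validate()
    if genotypes.n_loci != len(locus_map):
        raise FormatError("genotype matrix and locus map disagree on loci")
    genotypes.require_panels()
    n_imputed = genotypes.impute_missing()
    if n_imputed:
        log.info("mean-imputed %d missing genotype calls", n_imputed)
    root = np.random.SeedSequence(config.seed)
    het_ss, mcmc_ss, summary_ss = root.spawn(3)
    log.info(
        "fitting discriminant models: w=%d, %d loci, seed=%d",
        config.w,
        genotypes.n_loci,
        config.seed,
    )
    models = build_reference_models(
        genotypes.panel(PANEL_SOURCE_A),
        genotypes.panel(PANEL_SOURCE_B),
        locus_map,
        config.w,
        config.n_het,
        np.random.default_rng(het_ss),
        ridge=config.ridge,
    )
    grid = likelihood_grid(models, genotypes.panel(PANEL_ADMIXED))
    log.info(
        "running %d chain(s) of %d iterations (burn-in %d, thin %d)",
        config.chains,
        config.iters,
        config.burnin,
        config.thin,
    )
    chains = run_mcmc(grid, locus_map, config, seed=mcmc_ss)
    summary = summarize_posterior(
        chains,
        config,
        two_n=2.0 * grid.n_individuals,
        rng=np.random.default_rng(summary_ss),
    )
    log.info(
        "done: mean q=%.4f, sigma acceptance %.3f",
        float(summary.q_mean.mean()),
        summary.accept_sigma,
    )
    return summary
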