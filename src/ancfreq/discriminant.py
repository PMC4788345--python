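"""Windowed linear discriminant analysis of reference panels.

For every focal SNP a window of neighboring SNPs (same chromosome, up to
``w`` on either side) is projected onto the leading discriminant axis that
separates three reference groups: source-B individuals (0 gene copies from
source A), synthetic inter-population heterozygotes (1 copy), and source-A
individuals (2 copies).  The mean and variance of the reference scores in
each group turn an admixed individual's score into an unnormalized
likelihood of carrying 0, 1 or 2 source-A gene copies at the focal SNP.

The discriminant axis is the leading eigenvector of ``S_w^{-1} S_B`` where
``S_w`` is the pooled within-group covariance (group-centered cross-products
divided by ``sum_g n_g - 3``, plus a small ridge) and
``S_B = (1/3) sum_g (mu_g - mu)(mu_g - mu)^T`` is the between-group scatter
of the group means.  Only the first axis is needed because the heterozygote
group is intermediate between the two source groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ancfreq.datatypes import LocusMap
from ancfreq.errors import ConfigError, ConstraintError, FormatError, NumericalError

log = logging.getLogger(__name__)

LIKELIHOOD_FLOOR = 1e-300
_VAR_FLOOR_REL = 1e-6


@dataclass(frozen=True)
class Window:
    """Marker window around a focal SNP, confined to one chromosome."""

    focal: int
    members: np.ndarray  # sorted global row indices, focal included

    def __post_init__(self) -> None:
        members = np.asarray(self.members, dtype=np.int64)
        if self.focal not in members:
            raise ConstraintError("focal locus must be a window member")
        if np.any(np.diff(members) <= 0):
            raise ConstraintError("window members must be sorted and unique")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DiscriminantModel:
    """Fitted discriminant axis and reference score moments for one window."""

    window: Window
    coefficients: np.ndarray  # (P,)
    offsets: np.ndarray  # (P,) grand-mean column centering
    group_means: np.ndarray  # (3,) mean reference score for z = 0, 1, 2
    group_vars: np.ndarray  # (3,) reference score variances (floored)


@dataclass
class LikelihoodGrid:
    """Loci x admixed individuals x 3 ancestry-state likelihoods (Eq.-6 style).

    Entries are unnormalized normal densities of the individual's discriminant
    score under each reference group's score distribution; they are positive
    and finite but do not sum to one.
    """

    likelihoods: np.ndarray  # (L, n, 3)
    scores: np.ndarray  # (L, n)

    @property
    def n_loci(self) -> int:
        return self.likelihoods.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.likelihoods.shape[1]


def build_windows(locus_map: LocusMap, w: int, n_ref: int | None = None) -> list[Window]:
    """One window per locus: up to ``w`` SNPs on either side of the focal SNP.

    Windows never span chromosome boundaries; end-of-chromosome windows are
    truncated rather than shifted.  If ``n_ref`` (total reference sample
    count) is given, any window with at least that many members is rejected:
    the number of observations must exceed the number of variables in the
    discriminant analysis.
    """
    if w < 1:
        raise ConfigError("window half-width w must be >= 1")
    windows: list[Window] = []
    for sl in locus_map.chrom_slices().values():
        for x in range(sl.start, sl.stop):
            lo = max(sl.start, x - w)
            hi = min(sl.stop, x + w + 1)
            if n_ref is not None and hi - lo >= n_ref:
                raise ConstraintError(
                    f"window of {hi - lo} SNPs at locus {x} is not smaller than "
                    f"the {n_ref} reference individuals; the window cannot "
                    "include more SNPs than reference individuals"
                )
            windows.append(Window(focal=x, members=np.arange(lo, hi)))
    return windows


def simulate_het_references(
    ref_a: np.ndarray, ref_b: np.ndarray, n_het: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate reference individuals with one gene copy from each source.

    At each locus, each synthetic individual receives one allele drawn
    ``Bernoulli(g/2)`` from a randomly chosen source-A individual's genotype
    ``g`` and one drawn likewise from a random source-B individual, so the
    resulting counts lie in ``[0, 2]``.  Works for integer or posterior-mean
    real genotypes.
    """
    if n_het < 1:
        raise ConfigError("n_het must be >= 1")
    ref_a = np.asarray(ref_a, dtype=float)
    ref_b = np.asarray(ref_b, dtype=float)
    if ref_a.shape[0] != ref_b.shape[0]:
        raise FormatError("reference panels must cover the same loci")
    if ref_a.shape[1] == 0 or ref_b.shape[1] == 0:
        raise FormatError("both reference panels must be non-empty")
    n_loci = ref_a.shape[0]
    rows = np.arange(n_loci)[:, None]
    pick_a = rng.integers(0, ref_a.shape[1], size=(n_loci, n_het))
    pick_b = rng.integers(0, ref_b.shape[1], size=(n_loci, n_het))
    allele_a = rng.random((n_loci, n_het)) < ref_a[rows, pick_a] / 2.0
    allele_b = rng.random((n_loci, n_het)) < ref_b[rows, pick_b] / 2.0
    return allele_a.astype(float) + allele_b.astype(float)


def fit_discriminant(
    window: Window,
    group_blocks: tuple[np.ndarray, np.ndarray, np.ndarray],
    ridge: float = 1e-6,
) -> DiscriminantModel:
    """Fit the discriminant axis for one window.

    ``group_blocks`` holds the (members x window-SNPs) genotype blocks for the
    z = 0, 1, 2 reference groups in that order (individuals as rows).
    """
    g0, g1, g2 = (np.asarray(g, dtype=float) for g in group_blocks)
    p = len(window)
    n_tot = sum(g.shape[0] for g in (g0, g1, g2))
    for g in (g0, g1, g2):
        if g.shape[0] < 2:
            raise ConstraintError("each reference group needs >= 2 members")
        if g.shape[1] != p:
            raise FormatError("group block width disagrees with the window")
    if p >= n_tot:
        raise ConstraintError(
            "the window cannot include more SNPs than reference individuals"
        )
    stacked = np.vstack((g0, g1, g2))
    grand_mean = stacked.mean(axis=0)
    mus = [g.mean(axis=0) for g in (g0, g1, g2)]
    s_w = np.zeros((p, p))
    for g, mu in zip((g0, g1, g2), mus):
        c = g - mu
        s_w += c.T @ c
    s_w /= n_tot - 3
    s_w[np.diag_indices_from(s_w)] += ridge * max(np.mean(np.diag(s_w)), 1e-12)
    dev = np.stack(mus) - grand_mean  # (3, P)
    s_b = dev.T @ dev / 3.0
    try:
        eigvals, eigvecs = scipy.linalg.eigh(s_b, s_w)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(
            f"singular within-group covariance in window at locus "
            f"{window.focal}"
        ) from exc
    coef = np.real(eigvecs[:, -1])
    if not np.all(np.isfinite(coef)):
        raise NumericalError(
            f"non-finite discriminant coefficients at locus {window.focal}"
        )
    scores = [(g - grand_mean) @ coef for g in (g0, g1, g2)]
    if scores[2].mean() < scores[0].mean():
        coef = -coef
        scores = [-s for s in scores]
    group_means = np.array([s.mean() for s in scores])
    group_vars = np.array([s.var(ddof=1) for s in scores])
    pooled = np.concatenate(scores)
    floor = _VAR_FLOOR_REL * max(pooled.var(ddof=1), 1e-12)
    clamped = group_vars < floor
    if clamped.any():
        log.debug(
            "variance floor applied to group(s) %s at locus %d",
            np.where(clamped)[0].tolist(),
            window.focal,
        )
        group_vars = np.maximum(group_vars, floor)
    return DiscriminantModel(
        window=window,
        coefficients=coef,
        offsets=grand_mean,
        group_means=group_means,
        group_vars=group_vars,
    )


def score_individuals(model: DiscriminantModel, block: np.ndarray) -> np.ndarray:
    """Discriminant scores for a (individuals x window-SNPs) genotype block."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] != len(model.window):
        raise FormatError(
            "genotype block does not match the model's window loci"
        )
    return (block - model.offsets) @ model.coefficients


def likelihood_grid(
    models: list[DiscriminantModel], admixed: np.ndarray
) -> LikelihoodGrid:
    """Evaluate the 3-state score likelihood for every locus and individual.

    ``admixed`` is the full loci x individuals admixed genotype matrix
    (missing values imputed upstream).  Entry ``(x, j, g)`` is the normal
    density of individual ``j``'s score in window ``x`` under reference
    group ``g``'s score moments, floored at a tiny positive value.
    """
    admixed = np.asarray(admixed, dtype=float)
    n_loci = len(models)
    n_ind = admixed.shape[1]
    like = np.empty((n_loci, n_ind, 3))
    scores = np.empty((n_loci, n_ind))
    for x, model in enumerate(models):
        d = score_individuals(model, admixed[model.window.members, :].T)
        if not np.all(np.isfinite(d)):
            j = int(np.where(~np.isfinite(d))[0][0])
            raise NumericalError(
                f"non-finite discriminant score at locus {x}, individual {j}"
            )
        scores[x] = d
        var = model.group_vars
        dens = np.exp(-0.5 * (d[:, None] - model.group_means) ** 2 / var) / np.sqrt(
            2.0 * np.pi * var
        )
        like[x] = np.maximum(dens, LIKELIHOOD_FLOOR)
    return LikelihoodGrid(likelihoods=like, scores=scores)


def build_reference_models(
    ref_a: np.ndarray,
    ref_b: np.ndarray,
    locus_map: LocusMap,
    w: int,
    n_het: int | None,
    rng: np.random.Generator,
    ridge: float = 1e-6,
) -> list[DiscriminantModel]:
    """Fit one discriminant model per locus from the two reference panels.

    Synthetic heterozygote references are simulated once (default count
    ``round((n_A + n_B) / 2)``) and reused in every window.
    """
    if n_het is None:
        n_het = int(round((ref_a.shape[1] + ref_b.shape[1]) / 2))
    het = simulate_het_references(ref_a, ref_b, n_het, rng)
    n_ref = ref_a.shape[1] + n_het + ref_b.shape[1]
    windows = build_windows(locus_map, w, n_ref=n_ref)
    models = []
    for window in windows:
        m = window.members
        models.append(
            fit_discriminant(
                window,
                (ref_b[m].T, het[m].T, ref_a[m].T),
                ridge=ridge,
            )
        )
    return models
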