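"""Core domain types: locus maps, genotype matrices, run configuration,
and posterior summaries.

Conventions
-----------
* Genotypes are allele counts in ``[0, 2]`` (integer, or real-valued posterior
  mean genotypes); ``NaN`` marks a missing call.
* Loci are rows, individuals are columns.
* Positions are 1-based base pairs as in VCF; within each chromosome an
  internal 0-based marker index is derived.
* Chromosomes are fully independent units of computation: the smoothing
  kernel never crosses a chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ancfreq.errors import ConfigError, FormatError, LabelError, ValueRangeError

PANEL_SOURCE_A = "sourceA"
PANEL_SOURCE_B = "sourceB"
PANEL_ADMIXED = "admixed"
PANEL_LABELS = (PANEL_SOURCE_A, PANEL_SOURCE_B, PANEL_ADMIXED)


@dataclass(frozen=True)
class LocusMap:
    """Ordered marker map: chromosome id and base-pair position per marker.

    Markers must be grouped by chromosome with strictly increasing positions
    within each chromosome.  ``index_in_chrom`` gives the derived 0-based
    marker index used as the distance unit of the smoothing kernel.
    """

    chrom: np.ndarray  # (L,) str
    pos: np.ndarray  # (L,) int

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        if chrom.shape != pos.shape or chrom.ndim != 1:
            raise FormatError("chrom and pos must be 1-D arrays of equal length")
        if len(chrom) < 1:
            raise FormatError("locus map must contain at least one marker")
        if np.any(pos < 0):
            raise ValueRangeError("positions must be non-negative")
        # chromosomes must form contiguous blocks
        seen: set = set()
        prev = None
        for c in chrom:
            if c != prev:
                if c in seen:
                    raise FormatError(
                        f"markers of chromosome {c!r} are not contiguous"
                    )
                seen.add(c)
                prev = c
        for sl in _chrom_slices(chrom).values():
            p = pos[sl]
            if np.any(np.diff(p) <= 0):
                raise FormatError(
                    "positions must be strictly increasing within a chromosome"
                )
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> dict:
        """Mapping chromosome id -> slice of rows, in map order."""
        return _chrom_slices(self.chrom)

    @property
    def index_in_chrom(self) -> np.ndarray:
        """0-based marker index within each chromosome."""
        idx = np.empty(len(self), dtype=np.int64)
        for sl in self.chrom_slices().values():
            idx[sl] = np.arange(sl.stop - sl.start)
        return idx


def _chrom_slices(chrom: np.ndarray) -> dict:
    slices: dict = {}
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            slices[chrom[start]] = slice(start, i)
            start = i
    return slices


@dataclass
class GenotypeMatrix:
    """Loci x individuals allele-count matrix with panel labels.

    ``values`` entries lie in ``[0, 2]`` or are ``NaN`` (missing); labels are
    one of :data:`PANEL_LABELS` per individual.
    """

    values: np.ndarray  # (L, n) float
    ids: list
    labels: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("genotype values must be a 2-D matrix")
        if self.values.shape[1] != len(self.ids) or len(self.ids) != len(self.labels):
            raise FormatError("ids, labels and matrix columns disagree")
        bad = np.where(~np.isnan(self.values) & ((self.values < 0) | (self.values > 2)))
        if bad[0].size:
            x, j = bad[0][0], bad[1][0]
            raise ValueRangeError(
                f"genotype {self.values[x, j]!r} at locus {x}, individual "
                f"{self.ids[j]!r} outside [0, 2]"
            )
        unknown = set(self.labels) - set(PANEL_LABELS)
        if unknown:
            raise LabelError(f"unknown panel labels: {sorted(unknown)!r}")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    def panel(self, label: str) -> np.ndarray:
        """Sub-matrix (loci x members) for one panel label."""
        if label not in PANEL_LABELS:
            raise LabelError(f"unknown panel label {label!r}")
        return self.values[:, self.labels == label]

    def panel_ids(self, label: str) -> list:
        return [i for i, lab in zip(self.ids, self.labels) if lab == label]

    def require_panels(self) -> None:
        """Assert every panel is non-empty (precondition of the estimator)."""
        for label in PANEL_LABELS:
            if not np.any(self.labels == label):
                raise LabelError(f"panel {label!r} is empty")

    def impute_missing(self) -> int:
        """Mean-impute missing calls per locus within each panel, in place.

        Returns the number of imputed entries.  A locus that is entirely
        missing within a panel falls back to the overall panel mean of 1.0
        (an uninformative genotype).
        """
        n_imputed = 0
        for label in PANEL_LABELS:
            cols = np.where(self.labels == label)[0]
            if cols.size == 0:
                continue
            block = self.values[:, cols]
            miss = np.isnan(block)
            if not miss.any():
                continue
            with np.errstate(invalid="ignore"):
                locus_mean = np.nanmean(block, axis=1)
            locus_mean = np.where(np.isnan(locus_mean), 1.0, locus_mean)
            rows, jj = np.where(miss)
            block[rows, jj] = locus_mean[rows]
            self.values[:, cols] = block
            n_imputed += rows.size
        return n_imputed


@dataclass
class RunConfig:
    """Settings for the discriminant + MCMC estimation run.

    Parameters
    ----------
    w:
        Window half-width in SNPs; a window holds up to ``2 w + 1`` markers.
    alpha0, beta0:
        Shape parameters of the beta prior on ancestry frequencies
        (default 1, 1: uniform).
    sigma_min, sigma_max:
        Bounds of the uniform prior on the kernel scale, in squared
        marker-index units.
    sigma_step:
        Standard deviation of the log-scale random-walk proposal for sigma.
    chains, iters, burnin, thin:
        MCMC layout; draws are retained post burn-in every ``thin`` sweeps.
    epsilon:
        Kernel truncation tolerance: neighbors with weight below it are
        dropped from the weighted count sums.
    ridge:
        Relative ridge added to the within-group covariance
        (``ridge * mean diagonal``).
    n_het:
        Number of synthetic one-copy-from-each-source reference individuals;
        ``None`` means ``round((n_A + n_B) / 2)``.
    """

    w: int = 10
    alpha0: float = 1.0
    beta0: float = 1.0
    sigma_min: float = 0.01
    sigma_max: float = 1000.0
    sigma_step: float = 0.3
    chains: int = 2
    iters: int = 30_000
    burnin: int = 10_000
    thin: int = 5
    epsilon: float = 1e-6
    ridge: float = 1e-6
    n_het: int | None = None
    bb_intervals: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.w < 1:
            raise ConfigError("window half-width w must be >= 1")
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise ConfigError("prior shapes alpha0, beta0 must be positive")
        if not (0 < self.sigma_min < self.sigma_max):
            raise ConfigError("need 0 < sigma_min < sigma_max")
        if self.sigma_step <= 0:
            raise ConfigError("sigma proposal step must be positive")
        if self.chains < 1:
            raise ConfigError("need at least one chain")
        if not (0 <= self.burnin < self.iters):
            raise ConfigError("burn-in must be shorter than the total run")
        if self.thin < 1:
            raise ConfigError("thinning interval must be >= 1")
        if not (0 < self.epsilon < 1):
            raise ConfigError("kernel truncation epsilon must be in (0, 1)")
        if self.ridge <= 0:
            raise ConfigError("ridge must be positive")
        if self.n_het is not None and self.n_het < 1:
            raise ConfigError("n_het must be >= 1")


@dataclass
class PosteriorSummary:
    """Per-locus posterior summaries of the ancestry frequency q.

    ``q_low``/``q_high`` are the 2.5% and 97.5% quantiles of the pooled
    process-model draws; ``bb_low``/``bb_high`` are the matching equal-tail
    bounds of the beta-binomial interval fallback built from the latent
    ancestry counts.  ``dosage_mean`` is the posterior mean per-individual
    ancestry dosage (mean of the z draws, in [0, 2]).
    """

    q_mean: np.ndarray
    q_median: np.ndarray
    q_low: np.ndarray
    q_high: np.ndarray
    bb_low: np.ndarray | None
    bb_high: np.ndarray | None
    dosage_mean: np.ndarray  # (L, n_admixed)
    sigma_draws: np.ndarray  # (chains, n_draws)
    psrf_q: np.ndarray | None
    ess_q: np.ndarray
    psrf_sigma: float | None
    ess_sigma: float
    accept_sigma: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("q_mean", "q_median", "q_low", "q_high"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueRangeError(f"{name} outside [0, 1]")
        for lo, hi in ((self.q_low, self.q_high), (self.bb_low, self.bb_high)):
            if lo is not None and hi is not None and np.any(lo > hi):
                raise ValueRangeError("interval bounds out of order")
        if np.any((self.dosage_mean < 0) | (self.dosage_mean > 2)):
            raise ValueRangeError("dosage summaries outside [0, 2]")

    @property
    def n_loci(self) -> int:
        return len(self.q_mean)
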