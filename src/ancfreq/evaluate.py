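"""Accuracy metrics, the genome-average null model, the window-size
heuristic, and excess-ancestry region extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from ancfreq.datatypes import LocusMap
from ancfreq.errors import FormatError


@dataclass
class AccuracyReport:
    """Agreement between estimated and true per-locus ancestry frequencies.

    ``cvrmsd`` is the mean over loci of ``|q_hat - q| / q`` (loci with true
    frequency 0 are excluded from the mean and counted in
    ``n_zero_truth``); ``coverage`` is the fraction of loci whose true value
    lies inside the supplied 95% interval.  ``r_defined`` is False when the
    Pearson correlation is undefined (a constant vector), in which case
    ``r`` is reported as 0.
    """

    rmsd: float
    cvrmsd: float
    r: float
    r_defined: bool
    coverage: float | None
    n_zero_truth: int


def accuracy_metrics(
    q_est: np.ndarray,
    q_true: np.ndarray,
    intervals: tuple[np.ndarray, np.ndarray] | None = None,
) -> AccuracyReport:
    """RMSD, mean CVRMSD, Pearson r, and interval coverage of the truth."""
    q_est = np.asarray(q_est, dtype=float)
    q_true = np.asarray(q_true, dtype=float)
    if q_est.shape != q_true.shape or q_est.ndim != 1:
        raise FormatError("q_est and q_true must be equal-length vectors")
    err = q_est - q_true
    rmsd = float(np.sqrt(np.mean(err**2)))
    nonzero = q_true > 0
    cvrmsd = float(np.mean(np.abs(err[nonzero]) / q_true[nonzero]))
    if np.ptp(q_est) == 0 or np.ptp(q_true) == 0:
        r, r_defined = 0.0, False
    else:
        r = float(scipy.stats.pearsonr(q_est, q_true)[0])
        r_defined = True
    coverage = None
    if intervals is not None:
        low, high = (np.asarray(b, dtype=float) for b in intervals)
        if low.shape != q_true.shape or high.shape != q_true.shape:
            raise FormatError("interval bounds must match the loci")
        coverage = float(np.mean((q_true >= low) & (q_true <= high)))
    return AccuracyReport(
        rmsd=rmsd,
        cvrmsd=cvrmsd,
        r=r,
        r_defined=r_defined,
        coverage=coverage,
        n_zero_truth=int(np.sum(~nonzero)),
    )


def null_model(q: np.ndarray) -> np.ndarray:
    """Genome-average null: every locus gets the mean ancestry frequency."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise FormatError("empty frequency vector")
    return np.full_like(q, q.mean())


def expected_block_size(l_snp: int, t: int) -> float:
    """Expected SNPs per ancestry block on a 1-Morgan chromosome.

    The density of ancestry breakpoints across a pair of homologous
    chromosomes grows as t per Morgan, so blocks hold about ``L_SNP / t``
    SNPs; window half-widths should stay below this.  Slightly conservative:
    breakpoints form less often once ancestry frequencies leave 0.5, so true
    blocks run a little larger.  ``t = 0`` (no breakpoints) returns L_SNP.
    """
    if t < 0:
        raise FormatError("t must be >= 0")
    return float(l_snp) if t == 0 else l_snp / t


@dataclass(frozen=True)
class Region:
    """Contiguous run of loci beyond an empirical ancestry-frequency quantile."""

    chrom: str
    start: int  # bp, inclusive
    end: int  # bp, inclusive
    n_snps: int
    direction: str  # "high" or "low"


def excess_regions(
    q_est: np.ndarray,
    locus_map: LocusMap,
    lower_quantile: float = 0.0005,
    upper_quantile: float = 0.9995,
) -> list[Region]:
    """Merge loci beyond empirical quantiles into contiguous regions.

    A locus is flagged when its estimate is strictly below the lower or
    strictly above the upper empirical quantile value (ties at the threshold
    are not flagged).  Runs of consecutively flagged loci with the same
    direction on the same chromosome are merged; regions never cross
    chromosome boundaries.
    """
    q_est = np.asarray(q_est, dtype=float)
    if not (0 < lower_quantile < upper_quantile < 1):
        raise FormatError("need 0 < lower < upper < 1")
    if len(q_est) != len(locus_map):
        raise FormatError("estimates and locus map disagree on loci")
    lo_val, hi_val = np.quantile(q_est, [lower_quantile, upper_quantile])
    state = np.zeros(len(q_est), dtype=np.int8)
    state[q_est < lo_val] = -1
    state[q_est > hi_val] = 1
    regions: list[Region] = []
    for chrom, sl in locus_map.chrom_slices().items():
        run_start = None
        run_dir = 0
        for i in range(sl.start, sl.stop + 1):
            cur = state[i] if i < sl.stop else 0
            if cur != run_dir:
                if run_dir != 0:
                    regions.append(
                        Region(
                            chrom=str(chrom),
                            start=int(locus_map.pos[run_start]),
                            end=int(locus_map.pos[i - 1]),
                            n_snps=i - run_start,
                            direction="high" if run_dir > 0 else "low",
                        )
                    )
                run_start = i
                run_dir = cur
    return regions
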