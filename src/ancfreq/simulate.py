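"""Tract-based forward Wright-Fisher admixture simulator.

Individuals are tracked as ancestry tracts rather than genetic markers: each
haplotype of each chromosome is an alternating sequence of source-A / source-B
segments encoded by its breakpoint positions (in Morgans) and the label of the
first segment.  An admixed population of N diploids is founded either as a
50/50 mix of pure source-A and source-B individuals (the accuracy-study
condition) or as all F1s, and then evolves for t discrete Wright-Fisher
generations with:

* exactly one crossover per chromosome per meiosis, at a Uniform(0, L)
  position, starting from a randomly chosen parental haplotype;
* optional multiplicative underdominant selection, ``w_j = (1 - s)^{l_j}``
  with ``l_j`` the number of selected loci at which individual ``j`` carries
  one gene copy from each source;
* optional migration: with probability ``m`` an offspring is replaced by an
  unadmixed immigrant (pure source A or B with equal probability).

Marker genotypes are emitted afterwards: source-panel allele frequencies are
Uniform(0.05, 0.95) per marker, admixed copies draw alleles from
within-ancestry frequencies drifted under the Balding-Nichols beta model
``Beta(p * gamma, (1 - p) * gamma)`` with ``F = 1 - exp(-t / N)`` and
``gamma = (1 - F) / F``.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from ancfreq.datatypes import GenotypeMatrix, LocusMap
from ancfreq.errors import ConfigError

log = logging.getLogger(__name__)

LABEL_A = 1
LABEL_B = 0

# a haplotype is (breakpoints: list[float], first segment label: int);
# an individual is a list over chromosomes of (haplotype, haplotype) pairs.
Haplotype = tuple


@dataclass(frozen=True)
class SimConfig:
    """Admixture simulation settings.

    Defaults follow the study design the accuracy experiments use: N = 500
    diploids, two 1-Morgan chromosomes with 10,001 equally spaced markers
    each, 50 sampled individuals per panel, no selection or migration.
    ``drift_time_scale`` selects the Balding-Nichols fixation index formula:
    ``"N"`` gives F = 1 - exp(-t/N) (matching the t/N = 0.04, 0.10, 0.40
    ratios of the reference design), ``"2N"`` the 1 - exp(-t/2N) variant.
    """

    n_pop: int = 500
    t: int = 20
    n_chrom: int = 2
    chrom_length: float = 1.0  # Morgans
    markers_per_chrom: int = 10_001
    m: float = 0.0
    s: float = 0.0
    selected_loci: tuple = ()  # ((chrom index, position in Morgans), ...)
    n_sample_admixed: int = 50
    n_sample_source: int = 50
    drift_time_scale: str = "N"
    founding: str = "mix"
    bp_per_marker: int = 100

    def validate(self) -> None:
        if self.n_pop < 2:
            raise ConfigError("population size N must be >= 2")
        if self.t < 0:
            raise ConfigError("generations t must be >= 0")
        if not (0 <= self.m < 1):
            raise ConfigError("migration rate m must be in [0, 1)")
        if not (0 <= self.s < 1):
            raise ConfigError("selection coefficient s must be in [0, 1)")
        if self.n_chrom < 1 or self.markers_per_chrom < 2:
            raise ConfigError("need >= 1 chromosome with >= 2 markers")
        if self.n_sample_admixed > self.n_pop:
            raise ConfigError("cannot sample more individuals than N")
        for c, pos in self.selected_loci:
            if not (0 <= c < self.n_chrom) or not (0 <= pos <= self.chrom_length):
                raise ConfigError(f"selected locus ({c}, {pos}) outside the map")
        if self.drift_time_scale not in ("N", "2N"):
            raise ConfigError("drift_time_scale must be 'N' or '2N'")
        if self.founding not in ("mix", "f1"):
            raise ConfigError("founding must be 'mix' or 'f1'")

    @property
    def n_loci(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    def marker_positions(self) -> np.ndarray:
        """Equally spaced marker positions (Morgans) on one chromosome."""
        return np.linspace(0.0, self.chrom_length, self.markers_per_chrom)


@dataclass
class AncestryPanel:
    """Ground truth from one simulation: sampled tracts, dosage, q_true.

    ``hap_labels`` holds source-A indicators at every marker for each sampled
    haplotype, shaped (n_sample, 2, total loci) with chromosomes concatenated
    in map order; ``dosage`` is its sum over the two haplotypes; ``q_true``
    is the mean ancestry dosage over the whole population (all N diploids,
    not just the sample) divided by 2.
    """

    hap_labels: np.ndarray  # (n_sample, 2, L) int8
    dosage: np.ndarray  # (L, n_sample) int8
    q_true: np.ndarray  # (L,)
    sampled: list  # sampled individuals' tract representation
    config: SimConfig


@dataclass
class MarkerModel:
    """Per-marker source allele frequencies and their drifted counterparts."""

    p_a: np.ndarray
    p_b: np.ndarray
    p_a_drift: np.ndarray
    p_b_drift: np.ndarray
    fst: float
    gamma: float


def _label_at(hap: Haplotype, u: float) -> int:
    breaks, first = hap
    return first ^ (bisect.bisect_right(breaks, u) & 1)


def _gamete(pair, coin: int, u: float) -> Haplotype:
    """Transmitted haplotype: one crossover at ``u``, starting from
    ``pair[coin]``."""
    ha = pair[coin]
    hb = pair[1 - coin]
    ia = bisect.bisect_left(ha[0], u)
    ib = bisect.bisect_left(hb[0], u)
    la = ha[1] ^ (ia & 1)
    lb = hb[1] ^ (ib & 1)
    breaks = ha[0][:ia]
    if la != lb:
        breaks = breaks + [u]
    return (breaks + hb[0][ib:], ha[1])


def fitness(n_het_selected: int, s: float) -> float:
    """Multiplicative underdominant fitness ``(1 - s) ** l``."""
    return (1.0 - s) ** n_het_selected


def _het_counts(pop: list, selected_loci: tuple) -> np.ndarray:
    counts = np.zeros(len(pop), dtype=np.int64)
    for j, ind in enumerate(pop):
        l = 0
        for c, pos in selected_loci:
            h1, h2 = ind[c]
            if _label_at(h1, pos) != _label_at(h2, pos):
                l += 1
        counts[j] = l
    return counts


def _founding_population(cfg: SimConfig) -> list:
    """Generation 0 of the admixed population.

    ``founding="mix"`` (the accuracy-study condition) seeds half the
    population with pure source-A and half with pure source-B individuals, so
    the first hybrids form in generation 1; ``founding="f1"`` seeds every
    individual as an F1 (one pure-A and one pure-B haplotype per chromosome),
    the condition used for the ancestry-variance decay illustration.
    """
    pure_a: Haplotype = ([], LABEL_A)
    pure_b: Haplotype = ([], LABEL_B)
    if cfg.founding == "f1":
        return [
            [(pure_a, pure_b) for _ in range(cfg.n_chrom)] for _ in range(cfg.n_pop)
        ]
    half = cfg.n_pop // 2
    pop = [[(pure_a, pure_a) for _ in range(cfg.n_chrom)] for _ in range(half)]
    pop += [
        [(pure_b, pure_b) for _ in range(cfg.n_chrom)]
        for _ in range(cfg.n_pop - half)
    ]
    return pop


def _next_generation(pop: list, cfg: SimConfig, rng: np.random.Generator) -> list:
    n = cfg.n_pop
    if cfg.s > 0 and cfg.selected_loci:
        w = fitness(_het_counts(pop, cfg.selected_loci), cfg.s)
        parents = rng.choice(n, size=(n, 2), p=w / w.sum())
    else:
        parents = rng.integers(0, n, size=(n, 2))
    coins = rng.integers(0, 2, size=(n, 2, cfg.n_chrom))
    cross = rng.uniform(0.0, cfg.chrom_length, size=(n, 2, cfg.n_chrom))
    if cfg.m > 0:
        migrant = rng.random(n) < cfg.m
        migrant_label = rng.integers(0, 2, size=n)
    new_pop = []
    for j in range(n):
        if cfg.m > 0 and migrant[j]:
            lab = LABEL_A if migrant_label[j] else LABEL_B
            pure: Haplotype = ([], lab)
            new_pop.append([(pure, pure) for _ in range(cfg.n_chrom)])
            continue
        p1 = pop[parents[j, 0]]
        p2 = pop[parents[j, 1]]
        ind = []
        for c in range(cfg.n_chrom):
            g1 = _gamete(p1[c], int(coins[j, 0, c]), float(cross[j, 0, c]))
            g2 = _gamete(p2[c], int(coins[j, 1, c]), float(cross[j, 1, c]))
            ind.append((g1, g2))
        new_pop.append(ind)
    return new_pop


def _hap_marker_labels(hap: Haplotype, markers: np.ndarray) -> np.ndarray:
    """Source-A indicator of one haplotype at each marker position."""
    breaks, first = hap
    idx = np.searchsorted(np.asarray(breaks), markers, side="right")
    return (first ^ (idx & 1)).astype(np.int8)


def _population_labels(pop: list, cfg: SimConfig) -> np.ndarray:
    """(2N, L) source-A indicators for every haplotype in the population."""
    markers = cfg.marker_positions()
    out = np.empty((2 * len(pop), cfg.n_loci), dtype=np.int8)
    for j, ind in enumerate(pop):
        for k in range(2):
            row = []
            for c in range(cfg.n_chrom):
                row.append(_hap_marker_labels(ind[c][k], markers))
            out[2 * j + k] = np.concatenate(row)
    return out


def simulate_tracts(
    cfg: SimConfig,
    rng: np.random.Generator,
    per_generation=None,
) -> tuple[list, AncestryPanel]:
    """Run the tract simulation; returns (final population, AncestryPanel).

    ``per_generation(gen, population)``, if given, is called after every
    generation (including the founding generation 0).
    """
    cfg.validate()
    pop = _founding_population(cfg)
    if per_generation is not None:
        per_generation(0, pop)
    for gen in range(1, cfg.t + 1):
        pop = _next_generation(pop, cfg, rng)
        if per_generation is not None:
            per_generation(gen, pop)
    panel = sample_panel(pop, cfg, rng)
    return pop, panel


def sample_panel(pop: list, cfg: SimConfig, rng: np.random.Generator) -> AncestryPanel:
    """Sample admixed individuals without replacement and tabulate truth."""
    idx = rng.choice(cfg.n_pop, size=cfg.n_sample_admixed, replace=False)
    markers = cfg.marker_positions()
    n_s = cfg.n_sample_admixed
    hap_labels = np.empty((n_s, 2, cfg.n_loci), dtype=np.int8)
    sampled = [pop[i] for i in idx]
    for j, ind in enumerate(sampled):
        for k in range(2):
            hap_labels[j, k] = np.concatenate(
                [_hap_marker_labels(ind[c][k], markers) for c in range(cfg.n_chrom)]
            )
    all_labels = _population_labels(pop, cfg)
    q_true = all_labels.mean(axis=0)
    dosage = hap_labels.sum(axis=1).T.astype(np.int8)
    return AncestryPanel(
        hap_labels=hap_labels,
        dosage=dosage,
        q_true=q_true,
        sampled=sampled,
        config=cfg,
    )


def drift_allele_freq(
    p,
    t: int,
    n_pop: int,
    rng: np.random.Generator,
    time_scale: str = "N",
):
    """Balding-Nichols drifted allele frequency.

    ``F = 1 - exp(-t / N)`` (or ``-t / 2N``), ``gamma = (1 - F) / F``, and
    ``p' ~ Beta(p * gamma, (1 - p) * gamma)``, which preserves the mean and
    has variance ``p (1 - p) F``.  ``t = 0`` and fixed frequencies (0 or 1)
    are returned unchanged.
    """
    p = np.asarray(p, dtype=float)
    if t == 0:
        return p.copy() if p.ndim else float(p)
    denom = n_pop if time_scale == "N" else 2 * n_pop
    f = 1.0 - np.exp(-t / denom)
    gamma = (1.0 - f) / f
    interior = (p > 0) & (p < 1)
    out = p.copy() if p.ndim else np.atleast_1d(p.copy())
    pi = np.atleast_1d(p)[np.atleast_1d(interior)]
    if gamma <= 0:  # complete fixation: each marker lands on 0 or 1
        drawn = (rng.random(pi.shape) < pi).astype(float)
    else:
        drawn = rng.beta(pi * gamma, (1.0 - pi) * gamma)
    if p.ndim:
        out[interior] = drawn
        return out
    return float(drawn[0]) if interior else float(p)


def drift_parameters(t: int, n_pop: int, time_scale: str = "N") -> tuple[float, float]:
    """(F, gamma) of the Balding-Nichols drift model; F = 0 at t = 0."""
    denom = n_pop if time_scale == "N" else 2 * n_pop
    f = 1.0 - np.exp(-t / denom)
    gamma = np.inf if f == 0 else (1.0 - f) / f
    return float(f), float(gamma)


def draw_marker_model(cfg: SimConfig, rng: np.random.Generator) -> MarkerModel:
    """Uniform(0.05, 0.95) source frequencies plus drifted within-ancestry
    frequencies for the admixed population."""
    n = cfg.n_loci
    p_a = rng.uniform(0.05, 0.95, size=n)
    p_b = rng.uniform(0.05, 0.95, size=n)
    fst, gamma = drift_parameters(cfg.t, cfg.n_pop, cfg.drift_time_scale)
    p_a_drift = drift_allele_freq(p_a, cfg.t, cfg.n_pop, rng, cfg.drift_time_scale)
    p_b_drift = drift_allele_freq(p_b, cfg.t, cfg.n_pop, rng, cfg.drift_time_scale)
    return MarkerModel(
        p_a=p_a,
        p_b=p_b,
        p_a_drift=p_a_drift,
        p_b_drift=p_b_drift,
        fst=fst,
        gamma=gamma,
    )


def emit_genotypes(
    panel: AncestryPanel,
    marker_model: MarkerModel,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, LocusMap]:
    """Draw SNP genotypes for the two source panels and the admixed sample.

    Reference individuals draw allele counts Binomial(2, p) from their
    source's original frequencies; each admixed gene copy draws a Bernoulli
    allele from the drifted frequency of its true local ancestry.
    """
    n_src = cfg.n_sample_source
    n_adm = panel.hap_labels.shape[0]
    n_loci = cfg.n_loci
    ref_a = rng.binomial(2, marker_model.p_a[:, None], size=(n_loci, n_src))
    ref_b = rng.binomial(2, marker_model.p_b[:, None], size=(n_loci, n_src))
    p_copy = np.where(
        panel.hap_labels == LABEL_A,
        marker_model.p_a_drift[None, None, :],
        marker_model.p_b_drift[None, None, :],
    )
    alleles = rng.random(p_copy.shape) < p_copy
    admixed = alleles.sum(axis=1).T.astype(float)  # (L, n_adm)
    values = np.hstack([ref_a.astype(float), ref_b.astype(float), admixed])
    ids = (
        [f"A{i}" for i in range(n_src)]
        + [f"B{i}" for i in range(n_src)]
        + [f"adm{i}" for i in range(n_adm)]
    )
    labels = np.array(
        ["sourceA"] * n_src + ["sourceB"] * n_src + ["admixed"] * n_adm,
        dtype=object,
    )
    chrom = np.concatenate(
        [
            np.repeat(f"chr{c + 1}", cfg.markers_per_chrom)
            for c in range(cfg.n_chrom)
        ]
    )
    pos = np.concatenate(
        [
            np.arange(cfg.markers_per_chrom, dtype=np.int64) * cfg.bp_per_marker + 1
            for _ in range(cfg.n_chrom)
        ]
    )
    locus_map = LocusMap(chrom=chrom, pos=pos)
    return GenotypeMatrix(values=values, ids=ids, labels=labels), locus_map


def ancestry_summaries(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-generation ancestry variance decomposition of the whole population.

    Returns time series (length t + 1, generation 0 first) of the variance in
    genome-average ancestry among individuals, the variance in local ancestry
    frequencies among loci, and the mean proportion of loci at which
    individuals carry one gene copy from each source (inter-population
    ancestry).  Under ``founding="f1"`` generation 0 has individual variance
    0 and inter-population proportion 1.
    """
    var_ind, var_loci, interpop = [], [], []

    def record(gen: int, pop: list) -> None:
        labels = _population_labels(pop, cfg)  # (2N, L)
        dosage = labels[0::2] + labels[1::2]  # (N, L)
        genome_avg = dosage.mean(axis=1) / 2.0
        q = labels.mean(axis=0)
        var_ind.append(genome_avg.var())
        var_loci.append(q.var())
        interpop.append((dosage == 1).mean())

    simulate_tracts(cfg, rng, per_generation=record)
    return {
        "var_genome_avg": np.array(var_ind),
        "var_q": np.array(var_loci),
        "interpop_proportion": np.array(interpop),
    }


def true_block_size(panel: AncestryPanel, unit: str = "pair") -> float:
    """Mean ancestry-block size in SNPs among sampled individuals.

    With ``unit="pair"`` (default) a block is a maximal marker run over which
    the joint ancestry of a diploid pair of homologous chromosomes is
    constant, i.e. blocks are delimited by ancestry breakpoints on either
    homolog -- the scale on which the ``L_SNP / t`` breakpoint-density
    heuristic is defined.  With ``unit="haplotype"`` runs are measured on
    single haplotypes.  Returns the mean of per-chromosome-unit mean run
    lengths.
    """
    cfg = panel.config
    n_s, _, total = panel.hap_labels.shape
    means = []
    for j in range(n_s):
        for c in range(cfg.n_chrom):
            sl = slice(c * cfg.markers_per_chrom, (c + 1) * cfg.markers_per_chrom)
            if unit == "pair":
                state = panel.hap_labels[j, 0, sl] + 2 * panel.hap_labels[j, 1, sl]
                means.append(_mean_run_length(state))
            elif unit == "haplotype":
                for k in range(2):
                    means.append(_mean_run_length(panel.hap_labels[j, k, sl]))
            else:
                raise ConfigError("unit must be 'pair' or 'haplotype'")
    return float(np.mean(means))


def _mean_run_length(state: np.ndarray) -> float:
    change = np.flatnonzero(np.diff(state) != 0)
    bounds = np.concatenate(([0], change + 1, [len(state)]))
    return float(np.mean(np.diff(bounds)))


# ---------------------------------------------------------------------------
# presets: the simulation conditions of the reference accuracy study


def _diffuse_loci(cfg_chrom: int = 2, length: float = 1.0) -> tuple:
    per_chrom = 10
    return tuple(
        (c, float(p))
        for c in range(cfg_chrom)
        for p in (np.arange(1, per_chrom + 1) / (per_chrom + 1)) * length
    )


_PRESETS: dict[str, dict] = {
    "t20": {"t": 20},
    "t50": {"t": 50},
    "t200": {"t": 200},
    "t50_diffuse": {"t": 50, "s": 0.03, "selected_loci": _diffuse_loci()},
    "t50_strong": {
        "t": 50,
        "s": 0.3,
        "selected_loci": ((0, 1.0 / 3.0), (0, 2.0 / 3.0)),
    },
    "t200_m005": {"t": 200, "m": 0.005},
    "t200_m05": {"t": 200, "m": 0.05},
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str, markers_per_chrom: int = 10_001, **overrides) -> SimConfig:
    """Named simulation condition (one per accuracy-study row)."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {preset_names()}")
    kwargs = dict(_PRESETS[name])
    kwargs["markers_per_chrom"] = markers_per_chrom
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass
class SimResult:
    """Bundle of one simulated data set plus its ground truth."""

    genotypes: GenotypeMatrix
    locus_map: LocusMap
    panel: AncestryPanel
    marker_model: MarkerModel
    config: SimConfig
    seed: int

    @property
    def q_true(self) -> np.ndarray:
        return self.panel.q_true


def simulate_dataset(cfg: SimConfig, seed: int) -> SimResult:
    """Full pipeline input: tracts, drifted frequencies, emitted genotypes."""
    rng = np.random.default_rng(seed)
    _, panel = simulate_tracts(cfg, rng)
    model = draw_marker_model(cfg, rng)
    genotypes, locus_map = emit_genotypes(panel, model, cfg, rng)
    return SimResult(
        genotypes=genotypes,
        locus_map=locus_map,
        panel=panel,
        marker_model=model,
        config=cfg,
        seed=seed,
    )
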