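import numpy as np
import pytest

from ancfreq.datatypes import GenotypeMatrix, LocusMap
from ancfreq.simulate import (
    MarkerModel,
    emit_genotypes,
    preset,
    simulate_tracts,
)


@pytest.fixture(scope="session")
def tiny_locus_map() -> LocusMap:
    return LocusMap(
        chrom=np.array(["chr1", "chr1", "chr1", "chr2", "chr2"], dtype=object),
        pos=np.array([101, 201, 301, 101, 201]),
    )


@pytest.fixture(scope="session")
def tiny_genotypes(tiny_locus_map) -> GenotypeMatrix:
    rng = np.random.default_rng(0)
    values = rng.integers(0, 3, size=(5, 9)).astype(float)
    ids = [f"ind{i}" for i in range(9)]
    labels = np.array(
        ["sourceA"] * 3 + ["sourceB"] * 3 + ["admixed"] * 3, dtype=object
    )
    return GenotypeMatrix(values=values, ids=ids, labels=labels)


@pytest.fixture(scope="session")
def diagnostic_sim():
    """Small simulated data set with fully diagnostic markers.

    Blocks are kept much longer than both the analysis windows and the
    maximum kernel reach (t = 6 on a 2,000-marker chromosome), and the tiny
    population (N = 30) drifts quickly so ancestry frequencies carry real
    signal; per-individual ancestry is then recoverable almost everywhere.
    """
    cfg = preset(
        "t20",
        markers_per_chrom=2000,
        n_chrom=1,
        t=6,
        n_pop=30,
        n_sample_admixed=25,
        n_sample_source=40,
    )
    rng = np.random.default_rng(123)
    _, panel = simulate_tracts(cfg, rng)
    n = cfg.n_loci
    marker_model = MarkerModel(
        p_a=np.ones(n),
        p_b=np.zeros(n),
        p_a_drift=np.ones(n),
        p_b_drift=np.zeros(n),
        fst=0.0,
        gamma=np.inf,
    )
    genotypes, locus_map = emit_genotypes(panel, marker_model, cfg, rng)
    return cfg, panel, genotypes, locus_map


@pytest.fixture(scope="session")
def small_realistic_sim():
    """Realistic small data set (drifted frequencies, t=20) for smoke tests."""
    from ancfreq.simulate import simulate_dataset

    cfg = preset(
        "t20",
        markers_per_chrom=300,
        n_pop=120,
        n_sample_admixed=30,
        n_sample_source=40,
    )
    return simulate_dataset(cfg, seed=7)
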