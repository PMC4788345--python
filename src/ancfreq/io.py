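"""Readers and writers for the toolkit's file dialects.

Genotypes travel as a TSV with loci as rows, individuals as columns, and a
header row of individual ids; allele counts are in ``[0, 2]`` (real values
such as posterior-mean genotypes are accepted) with ``NA`` for missing.  A
companion map TSV (``chrom``, ``pos``, 1-based) and panel TSV (``id``,
``label``) complete a data set.  Biallelic unphased VCF input is supported as
an alternative genotype source.  Posterior summaries are written as a
per-locus TSV track, optionally alongside an HDF5 container of raw thinned
MCMC draws keyed by chain and parameter.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ancfreq.datatypes import PANEL_LABELS, GenotypeMatrix, LocusMap, PosteriorSummary
from ancfreq.errors import FormatError, LabelError

log = logging.getLogger(__name__)

SUMMARY_FLOAT_FMT = "%.6f"


def _read_panels(panel_path) -> dict:
    panels = pd.read_csv(panel_path, sep="\t", dtype=str)
    if list(panels.columns) != ["id", "label"]:
        raise FormatError("panel file must have columns: id, label")
    unknown = set(panels["label"]) - set(PANEL_LABELS)
    if unknown:
        raise LabelError(f"unknown panel labels: {sorted(unknown)!r}")
    return dict(zip(panels["id"], panels["label"]))


def read_locus_map(map_path) -> LocusMap:
    m = pd.read_csv(map_path, sep="\t", dtype={"chrom": str, "pos": np.int64})
    if list(m.columns) != ["chrom", "pos"]:
        raise FormatError("map file must have columns: chrom, pos")
    return LocusMap(chrom=m["chrom"].to_numpy(dtype=object), pos=m["pos"].to_numpy())


def read_genotypes(
    genotype_path, map_path, panel_path
) -> tuple[GenotypeMatrix, LocusMap]:
    """Read the genotype/map/panel TSV triplet into validated objects."""
    locus_map = read_locus_map(map_path)
    table = pd.read_csv(genotype_path, sep="\t", na_values=["NA"])
    ids = [str(c) for c in table.columns]
    values = table.to_numpy(dtype=float)
    if values.shape[0] != len(locus_map):
        raise FormatError(
            f"genotype file has {values.shape[0]} loci but the map has "
            f"{len(locus_map)} rows"
        )
    label_of = _read_panels(panel_path)
    missing = [i for i in ids if i not in label_of]
    if missing:
        raise LabelError(f"individuals without a panel label: {missing!r}")
    labels = np.array([label_of[i] for i in ids], dtype=object)
    gm = GenotypeMatrix(values=values, ids=ids, labels=labels)
    n_missing = int(np.isnan(gm.values).sum())
    if n_missing:
        log.info("read %d missing genotype calls (flagged, not imputed)", n_missing)
    return gm, locus_map


def read_vcf(vcf_path, panel_path) -> tuple[GenotypeMatrix, LocusMap]:
    """Read biallelic SNPs from a VCF into allele counts of the ALT allele.

    Unphased genotypes are accepted; missing calls become ``NaN``.  Sites
    that are not biallelic SNPs are skipped with a log message.
    """
    from cyvcf2 import VCF  # deferred: VCF support is optional

    vcf = VCF(str(vcf_path))
    ids = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            skipped += 1
            continue
        types = variant.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        counts = np.choose(types, [0.0, 1.0, np.nan, 2.0])
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        rows.append(counts)
    if skipped:
        log.info("skipped %d non-biallelic or non-SNP records", skipped)
    if not rows:
        raise FormatError("no biallelic SNPs found in VCF")
    locus_map = LocusMap(
        chrom=np.array(chroms, dtype=object), pos=np.array(positions, dtype=np.int64)
    )
    label_of = _read_panels(panel_path)
    missing = [i for i in ids if i not in label_of]
    if missing:
        raise LabelError(f"individuals without a panel label: {missing!r}")
    labels = np.array([label_of[i] for i in ids], dtype=object)
    gm = GenotypeMatrix(values=np.vstack(rows), ids=ids, labels=labels)
    return gm, locus_map


def write_genotypes(
    gm: GenotypeMatrix, locus_map: LocusMap, genotype_path, map_path, panel_path
) -> None:
    """Write the TSV triplet that :func:`read_genotypes` reads back."""
    pd.DataFrame(gm.values, columns=gm.ids).to_csv(
        genotype_path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    pd.DataFrame({"chrom": locus_map.chrom, "pos": locus_map.pos}).to_csv(
        map_path, sep="\t", index=False
    )
    pd.DataFrame({"id": gm.ids, "label": list(gm.labels)}).to_csv(
        panel_path, sep="\t", index=False
    )


def write_summary(
    summary: PosteriorSummary,
    locus_map: LocusMap,
    summary_path,
    draws_path=None,
) -> None:
    """Write the per-locus summary TSV (and optionally raw draws to HDF5)."""
    if summary.n_loci != len(locus_map):
        raise FormatError("summary and locus map disagree on loci")
    nan = np.full(summary.n_loci, np.nan)
    table = pd.DataFrame(
        {
            "chrom": locus_map.chrom,
            "pos": locus_map.pos,
            "q_mean": summary.q_mean,
            "q_median": summary.q_median,
            "q_low": summary.q_low,
            "q_high": summary.q_high,
            "bb_low": summary.bb_low if summary.bb_low is not None else nan,
            "bb_high": summary.bb_high if summary.bb_high is not None else nan,
        }
    )
    table.to_csv(summary_path, sep="\t", index=False, float_format="%.6f", na_rep="NA")
    if draws_path is not None:
        write_sigma_draws(summary.sigma_draws, draws_path)


def write_sigma_draws(sigma_draws: np.ndarray, path) -> None:
    """Store raw thinned draws in an HDF5 container keyed by chain."""
    import h5py

    with h5py.File(path, "w") as h5:
        for c in range(sigma_draws.shape[0]):
            h5.create_dataset(f"chain{c}/sigma", data=sigma_draws[c])


def read_sigma_draws(path) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as h5:
        chains = sorted(h5.keys(), key=lambda k: int(k.removeprefix("chain")))
        return np.stack([h5[f"{c}/sigma"][()] for c in chains])


def read_summary(summary_path) -> pd.DataFrame:
    """Read a summary TSV back into a data frame (round-trip of writer)."""
    return pd.read_csv(summary_path, sep="\t", na_values=["NA"], dtype={"chrom": str})


def write_truth(panel, locus_map: LocusMap, truth_path) -> None:
    """Per-locus true ancestry frequency plus per-individual true dosage."""
    cols = {
        "chrom": locus_map.chrom,
        "pos": locus_map.pos,
        "q_true": panel.q_true,
    }
    for j in range(panel.dosage.shape[1]):
        cols[f"dosage_adm{j}"] = panel.dosage[:, j]
    pd.DataFrame(cols).to_csv(truth_path, sep="\t", index=False, float_format="%.6f")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
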