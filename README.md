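# ancfreq

Population-level **local ancestry frequency** inference for admixed
populations, from un-phased SNP genotypes.

Admixture between two populations (A and B) followed by recombination,
drift, and selection leaves each genome a mosaic of ancestry tracts. While
an admixed population is still segregating for ancestry — admixture old
enough that genome-average ancestry has homogenized, but before local
ancestry blocks fix — the interesting quantity is the *population ancestry
frequency* `q_x`: the proportion of gene copies at SNP `x` inherited from
source A, which varies along the genome. `ancfreq` estimates `q_x` (with
credible intervals, and per-individual ancestry dosages as a by-product)
for researchers studying hybrid zones, admixed human populations, genome
stabilization, or admixture mapping, using only unphased allele counts and
reference panels from the two sources — the kind of data
genotyping-by-sequencing delivers for non-model organisms.

## Model

At each SNP, each admixed diploid carries `z_xj ∈ {0, 1, 2}` source-A gene
copies, `z_x = Σ_j z_xj` out of `2n_x`. Two ideas are combined:

1. **Windowed discriminant analysis.** For each focal SNP, a window of up
   to `w` SNPs on either side is projected onto the leading eigenvector of
   `S_w⁻¹S_B` (pooled within-group covariance vs between-group scatter)
   fit on three reference groups: source-B panel (`z=0`), source-A panel
   (`z=2`), and simulated inter-population heterozygotes (`z=1`). The
   per-group score moments give a likelihood
   `Pr(s_xj | z_xj = g) = N(d_xj; d̄_g, var(d_g))`.

2. **A continuous correlated beta process** couples linked loci: with the
   squared-exponential kernel `k(x,i) = exp(−(x−i)²/σ)`,

       q_x | z, σ  ~  Beta(α₀ + Σᵢ zᵢ k(x,i),  β₀ + Σᵢ (2nᵢ − zᵢ) k(x,i)),

   so each locus borrows ancestry counts from its neighbors at a scale σ
   learned from the data.

Gibbs updates for `z` (categorical ∝ likelihood × Binomial(2, q_x) prior)
and `q`, plus a Metropolis update for σ, yield posterior summaries per
locus: mean, median, 95% equal-tail intervals, and a **beta-binomial
interval fallback** (`Beta(z_x + α₀, 2n_x − z_x + β₀)` per retained draw)
that resists the interval narrowing caused by kernel pooling. A
tract-based Wright–Fisher admixture simulator (drift, underdominant
selection, migration, Balding–Nichols allele-frequency drift) and an
evaluation harness (RMSD, CVRMSD, Pearson r, interval coverage,
genome-average null model, excess-ancestry regions) make the accuracy
study reproducible end to end without external data. See
[`docs/methods.md`](docs/methods.md) for the full account.

## Worked example

Simulate an admixed population (N = 500 diploids, t = 20 generations after
a 50/50 founding, two 1-Morgan chromosomes with 500 SNPs each, 50
individuals sampled per panel), estimate, and evaluate:

```sh
ancfreq simulate --preset t20 --markers 500 --seed 42 -o sim/
ancfreq estimate -i sim/genotypes.tsv -m sim/map.tsv -p sim/panels.tsv \
    -w 10 --iters 6000 --burnin 2000 --thin 5 --seed 1 -o est/
ancfreq evaluate --estimate est/summary.tsv --truth sim/truth.tsv -o metrics.json
```

`est/summary.tsv` holds one row per SNP:

```
chrom  pos  q_mean     q_median   q_low      q_high     bb_low     bb_high
chr1   1    0.370079   0.370348   0.345933   0.391448   0.240286   0.444567
chr1   101  0.370795   0.371101   0.348116   0.393279   0.232476   0.455418
```

i.e. at the first SNP an estimated 37% of gene copies are source-A, with a
[0.35, 0.39] process-model interval and a wider, better-calibrated
[0.24, 0.44] beta-binomial interval. `metrics.json` scores the run against
the simulator's ground truth:

```
method: r = 0.831,  RMSD = 0.042,  CVRMSD = 0.065,  coverage = 0.33
method beta-binomial coverage = 0.947
null (genome-average) model:   RMSD = 0.074,  CVRMSD = 0.124
```

The estimates correlate strongly with the true frequencies and halve the
null model's error; the process-model intervals are too narrow (a known
property of the pooled update — see the methods note) while the
beta-binomial intervals cover the truth 95% of the time.
`ancfreq regions` extracts contiguous runs of loci beyond empirical
quantiles of `q` — candidate regions of excess ancestry.

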