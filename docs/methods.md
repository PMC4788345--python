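# Methods

`ancfreq` estimates population-level local ancestry frequencies in an
admixed population descended from two source populations, using un-phased
SNP allele counts. This note documents the model, the algorithmic and
numerical choices, the synthetic-data generator, and known limitations.

## Problem setting

Consider an admixed population founded `t` generations ago by hybridization
between sources A and B, evolving since by recombination, drift, and
possibly selection, with little or no ongoing gene flow. At each SNP `x`,
each diploid individual `j` carries `z_xj ∈ {0, 1, 2}` gene copies of
source-A ancestry; the population ancestry frequency is `q_x`. Before
genome stabilization completes, `q_x` varies along the genome — the
quantity of interest — while methods built for either very recent or fully
stabilized admixture assume it does not.

## Per-individual ancestry likelihoods from SNP windows

Single SNPs are weakly informative about local ancestry (sources share
variation and allele frequencies drift). `ancfreq` therefore scores each
individual on a window of up to `w` SNPs on either side of the focal SNP
(truncated at chromosome ends, never crossing a chromosome boundary) using
linear discriminant analysis on three reference groups:

* source-B panel (`z = 0`), source-A panel (`z = 2`), both observed;
* synthetic inter-population heterozygotes (`z = 1`), built by drawing one
  Bernoulli(g/2) allele from a random A individual and one from a random B
  individual at each locus. Their count defaults to `round((n_A + n_B)/2)`,
  balancing the design; no published count exists for this group.

With grand-mean-centered window genotypes, the pooled within-group
covariance is `S_w = Σ_g (X_g − μ_g)ᵀ(X_g − μ_g) / (Σ_g n_g − 3)` plus a
ridge `δ·mean(diag(S_w))·I` (default relative ridge `δ = 1e-6`; monomorphic
windows occur in real data), and the between-group scatter is
`S_B = (1/3) Σ_g (μ_g − μ)(μ_g − μ)ᵀ`. The discriminant axis is the leading
eigenvector of `S_w⁻¹ S_B`, computed via the symmetric generalized
eigenproblem `S_B v = λ S_w v` and sign-fixed so that the `z = 2` group
scores above the `z = 0` group (making results independent of eigensolver
conventions). Only the first axis is used: the heterozygote group is
intermediate by construction.

The score likelihood is `Pr(s_xj | z_xj = g) = N(d_xj; d̄_g, var(d_g))`
with moments taken from the reference scores; group variances are floored
at `1e-6` of the pooled score variance, and densities at `1e-300`, to keep
perfectly separable (fully diagnostic) windows finite. Because the moments
come from the same references the axis was fit on, they are mildly
overconfident for fresh individuals; this is inherited from the method's
design. Windows must contain fewer SNPs than the total reference count
(observations must exceed variables); violating configurations are
rejected with an explicit error.

Missing genotypes are mean-imputed per locus within each panel before the
analysis (the DA needs complete vectors); imputation counts are logged.
Real-valued posterior-mean genotypes are accepted throughout.

## The correlated beta process sampler

Ancestry frequencies at linked loci are autocorrelated, so counts are
shared across loci through a squared-exponential kernel
`k(x, i) = exp(−(x − i)² / σ)` in marker-index distance (the simulated
designs have equally spaced markers; physical/map distance would only
rescale σ). The generalized conditional for each locus is

    q_x | z, σ ~ Beta(α₀ + Σ_i z_i k(x,i),  β₀ + Σ_i (2n_i − z_i) k(x,i)),

with `α₀ = β₀ = 1` by default (a uniform prior on q). Kernel weights below
`ε = 1e-6` are truncated, which bounds the stencil half-width at
`√(σ·ln(1/ε))` markers and makes the per-sweep cost linear in loci; the
weighted sums are evaluated as per-chromosome convolutions.

One MCMC sweep updates, in order:

1. every `z_xj` by Gibbs from the categorical ∝
   `Pr(s_xj | z_xj = g) · C(2,g) q_x^g (1−q_x)^{2−g}` (three-way underflow
   is floored and renormalized, with a logged warning);
2. every `q_x` by Gibbs from the beta conditional above (kernel stencil
   rebuilt first if σ changed);
3. σ by a random-walk Metropolis step on log σ with step 0.3 under a
   uniform prior on `[0.01, 1000]` (squared-index units). The acceptance
   ratio multiplies the beta-conditional density ratio by the proposal
   Jacobian `σ'/σ`; without that factor the sampler would target a prior
   uniform in log σ rather than in σ. Out-of-bounds proposals are
   rejected. No adaptive tuning; the acceptance rate is logged.

Chains initialize `z` at the per-cell maximum-likelihood state of the
grid, `q` at the implied sample frequency, and σ at the arithmetic
midpoint of its prior. The midpoint choice matters: given a fixed `z`, the
beta conditionals integrate to one for every σ, so σ's conditional
stationary distribution is exactly its prior and the chain is tethered to
the data only through the z-feedback loop. The log random walk explores
this nearly flat landscape slowly, and a start deep in the low tail (e.g.
the geometric midpoint, ~3.2) cannot reach the prior's mass center within
practical run lengths, leaving σ's PSRF far above 1. This weak
identifiability of σ is a property of the generalized update, not of the
implementation; it is also why the interval fallback below exists.

Defaults: 2 chains, 30,000 iterations, 10,000 burn-in, thinning 5 (the
desk-scale experiments use 6,000/2,000/5 as documented below). Retained
draws are pooled into per-locus posterior mean, median, and 95% equal-tail
probability intervals (ETPIs), plus per-individual posterior-mean dosage.
Convergence is summarized by the (non-split) Gelman–Rubin PSRF across
chains and by an effective sample size from Geyer's initial-positive-
sequence autocorrelation estimator, cross-checked against `arviz` in the
test suite.

### Beta-binomial interval fallback

Kernel pooling sharpens point estimates but unduly narrows the process
posterior for `q_x`, so its 95% ETPIs under-cover. As a remedy, for every
retained `z` draw one value is sampled from
`Beta(z_x + α₀, 2n_x − z_x + β₀)` — the single-locus conjugate posterior —
and the equal-tail quantiles of those draws are reported alongside
(`bb_low`/`bb_high`). These intervals retain the per-locus sampling
uncertainty and are never narrower in practice; the evaluation suite
verifies that they cover the truth more often than the process-model
intervals on selection data sets.

## Synthetic data generator

The simulator is the package's study harness: it defines the conditions
under which accuracy is assessed, and all test inputs are generated by it
at run time.

Individuals are tracked as ancestry tracts (breakpoint lists per
haplotype), not marker arrays. Generation 0 is, by default, a 50/50 mix of
pure source-A and source-B individuals ("mix" founding); strict F1
founding is available (`founding="f1"`) and is used for the
variance-decay illustration, which is defined for an all-F1 start. The mix
default was chosen because it reproduces the reference design's measured
mean block sizes at every time depth (t = 20, 50, 200), where F1 founding
overshoots the breakpoint density at t = 20; with mix founding the first
hybrids appear in generation 1 and roughly half of all crossovers fall
where homologs differ in ancestry.

Each Wright-Fisher generation draws parents with replacement (selfing
allowed) with probabilities ∝ `w_j = (1 − s)^{l_j}` (multiplicative
underdominance; `l_j` counts selected loci with one gene copy from each
source), forms each transmitted gamete with exactly one crossover per
chromosome at a Uniform(0, L) position starting from a fair-coin haplotype,
and replaces each offspring with probability `m` by an unadmixed immigrant
(pure A or B, fair coin). Chromosomes are 1 Morgan with equally spaced
markers (defaults: 2 chromosomes × 10,001 markers).

Genotypes are emitted at the end: source panels draw Binomial(2, p) counts
from per-marker frequencies `p ~ Uniform(0.05, 0.95)`; admixed gene copies
draw Bernoulli alleles from within-ancestry frequencies drifted once per
(marker, ancestry) under the Balding–Nichols model
`p' ~ Beta(pγ, (1−p)γ)` with `F = 1 − exp(−t/N)` and `γ = (1−F)/F`
(variance `p(1−p)F`). The `F = 1 − exp(−t/2N)` variant is available
(`drift_time_scale="2N"`); the default matches the reference design's
stated time/size ratios (0.04, 0.10, 0.40 for t = 20, 50, 200 at N = 500).
Reference panels are drawn from the undrifted source frequencies — drift
within the admixed population is what makes the inference realistic and
hard. `γ = 0` (complete fixation) degenerates to a Bernoulli(p) draw.

Selected-locus placement: the diffuse preset (s = 0.03, L = 20) spaces 10
loci evenly along each chromosome; the strong preset (s = 0.3, L = 2) puts
both loci on chromosome 1 at 1/3 and 2/3 of its length. Positions are
configurable; published descriptions give counts and chromosome
assignment only.

True ancestry block size is measured on the diploid pair: a block is a
maximal marker run over which the joint ancestry of both homologs is
constant (delimited by a breakpoint on either homolog), matching the scale
of the `L_SNP/t` breakpoint-density heuristic; per-chromosome-pair mean run
lengths are averaged. A per-haplotype variant is provided.

What the generator does **not** emulate: background linkage disequilibrium
within sources (marker frequencies are independent), variable
recombination maps, sex chromosomes, more than two sources, genotyping
error, and missingness patterns of real assays. Passing tests therefore
demonstrate correct behavior under the model's own assumptions, not
robustness to their violation.

## Evaluation harness

* **RMSD** `√(mean (q̂ − q)²)` and **CVRMSD**: per-locus `|q̂_x − q_x|/q_x`
  averaged over loci with `q_x > 0` (zero-truth loci are excluded and
  counted). The per-locus reading of "RMSD divided by the true value" is
  used; a per-replicate global reading also exists in the literature, and
  the locus-wise mean is what an "average CVRMSD" denotes here.
* **Pearson r** between estimate and truth; a constant vector makes it
  undefined, reported as 0 with a flag.
* **Coverage**: fraction of loci whose true frequency falls inside the 95%
  interval (process-model or beta-binomial).
* **Null model**: every locus assigned the genome-average frequency — the
  no-variation baseline any useful estimator must beat on CVRMSD.
* **Window heuristic**: expected block size `L_SNP/t` SNPs for a 1-Morgan
  chromosome (breakpoint density t per Morgan per homolog pair); window
  half-widths should stay below it. `t = 0` returns `L_SNP`.
* **Excess regions**: loci strictly beyond empirical quantiles of the
  estimates, merged into runs of equal direction within chromosomes.
  Strict inequality makes tie behavior deterministic and conservative
  (a constant vector yields no regions).

## Scales used in the shipped experiments

The full reference design (2 × 10,001 markers, 10 replicates, 30,000-
iteration chains) runs in hours; the package's experiments are sized for a
desktop. Tract-level statistics (block sizes, fixation proportions) run at
the full design size with 10 replicates — the tract simulator is cheap.
The estimation experiments run at 2,000 markers per chromosome with 3
replicates and 2 × 6,000-iteration chains (2,000 burn-in, thin 5), as
recorded in `scripts/acceptance.py`.

This rescaling preserves everything except marker density per Morgan, and
that one difference matters: a ±20-SNP window spans 2.1 cM at 2,000
markers/chromosome versus 0.41 cM at 10,001, so windows straddle ancestry
breakpoints about five times as often, and at t = 200 a block holds ~10
SNPs — smaller than the window itself. Correlations at t = 20 and under
strong selection reproduce the full-scale values; the t = 200 correlation
and the process-model interval coverage fall short of them at this
density, consistently with that geometry. The beta-binomial fallback's
higher coverage, and its contrast with the process-model intervals, is
reproduced.

## Known limitations

* Two source populations only; un-phased data only (phase, if known, is
  ignored).
* σ is weakly identified (prior-dominated given fixed latent ancestry);
  treat it as a nuisance smoothing scale, not an estimand, and treat the
  process-model ETPIs as optimistic — prefer the beta-binomial intervals
  for uncertainty statements.
* The generalized update is not a coherent joint posterior; chains sample
  an approximation, and PSRF/ESS should be checked per run (they are
  reported in every summary).
* Reference score moments are in-sample and mildly overconfident;
  quadratic/shrinkage discriminants and alternative likelihood engines are
  out of scope.
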