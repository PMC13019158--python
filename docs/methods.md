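# Methods

This note documents the statistical models behind `popimmune`, the
defaults that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Genetic differentiation

Per bi-allelic autosomal site, allele frequencies are estimated per
population from alternate-allele dosages, excluding missing calls from
both numerator and denominator. The fixation index is computed in the
Nei G_ST form

    F_ST = (H_T − H_S) / H_T,
    H_T = 2 p̄ (1 − p̄),   H_S = mean_k 2 p_k (1 − p_k),

with p̄ the **unweighted** mean across populations (the 1000 Genomes-style
super-populations this targets are near-balanced; a sample-size-weighted
variant is available via `site_fst(..., weighted=True)`). Sites that are
monomorphic in the pooled sample have H_T = 0 and are flagged undefined;
they are excluded from per-gene aggregates (mean and max of per-site
F_ST). Small negative values from finite sampling are reported as
computed; `clamp_zero=True` truncates them. Pairwise population matrices
apply the same statistic to each pair and are symmetric with a zero
diagonal. Ploidy is fixed at 2 and sex chromosomes are out of scope.

**Finite-deme bias and `bn_f_estimate`.** G_ST equals the across-
population frequency variance (1/K denominator) divided by p̄(1 − p̄).
Under a superpopulation model in which deme frequencies are exchangeable
draws with variance F·p(1−p) (Balding-Nichols), its expectation is
approximately F(1 − 1/K)/(1 − F/K) — at K = 5 and F = 0.1 that is 0.082,
a systematic 18% shortfall that no amount of sites repairs. The
descriptive statistic is kept exactly as defined because its closed forms
(fixed difference → 1; p = (0.2, 0.8) → 0.36) are the published
convention. Parameter recovery is instead measured with
`bn_f_estimate`: the unbiased (K − 1 denominator) frequency variance,
minus the mean binomial sampling variance of the per-population frequency
estimates, divided by an unbiased estimate of p(1−p), combined across
sites as a ratio of sums to avoid per-site Jensen bias. On simulations at
targets {0.02, 0.05, 0.1, 0.2} it recovers F within ±0.005 with a
regression slope of ~1.0, while the G_ST mean tracks the analytic biased
expectation — both behaviors are asserted in the test suite.

Genotype QC retains sites with pooled call rate strictly greater than
0.95 and pooled MAF strictly greater than 0.01.

## McDonald-Kreitman selection statistics

For per-gene counts of nonsynonymous/synonymous polymorphism (Pn, Ps) and
fixed divergence (Dn, Ds):

    NI  = (Pn/Ps) / (Dn/Ds)
    α   = 1 − (Pn·Ds) / (Ps·Dn)
    DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps)

α + NI = 1 exactly whenever both are defined, and the DoS sign agrees
with the α sign. Zero denominators flag NI/α undefined rather than being
patched; DoS is reported whenever both marginal totals are positive. An
optional +0.5 pseudocount on every cell (exploratory only) restores
definedness. The p-value is a two-sided exact test on
[[Pn, Ps], [Dn, Ds]]; extraction of the counts from alignments is
upstream and out of scope. `pooled_mk` sums counts across genes before
applying the same formulas, which stabilizes α.

## Pre-ranked enrichment

Rankings are strictly ordered by (score descending, identifier
ascending) so ties resolve identically on every platform. With hit
weights |score|^q (q = 1 by default; q = 0 gives the unweighted
Kolmogorov-Smirnov form), the running sum gains
|score|^q / Σ_hits |score|^q at hits and loses 1/(N − n_hits) at misses;
the ES is the signed maximum-magnitude deviation. The null resamples
identifier labels of the set's size without replacement (pre-ranked input
has no sample structure to permute), and the two-sided p-value
(1 + #{|ES_null| ≥ |ES_obs|}) / (1 + n_perm) never reaches zero. A set
spanning the whole list is degenerate and reported with p = 1.
Benjamini-Hochberg adjustment is order-invariant and deterministic (note
BH is *not* idempotent: re-adjusting adjusted values inflates them
again). Pathway-level F_ST profiles use the gene-level mean by default; a
site-count-weighted variant is exposed because "average F_ST of the
nsSNPs in a pathway's genes" is ambiguous between the two readings.

## nsSNP prioritization

Genotype calls from multiple platforms merge cell-wise by fixed priority
SNP array > WES > imputation, recording provenance; conflicting ref/alt
site definitions are an error. The candidate filter applies, in order:
(1) host gene in the sensor-pathway gene list; (2) host gene FPKM > 1 in
more than 95% of cell lines; (3) host gene max F_ST > 0.1; (4) pooled
MAF > 0.2 — with survivor tallies after each step.

Per candidate SNP, samples split into reference homozygotes vs carriers
(dosage ≥ 1; `group_mode="hom"` contrasts the homozygote classes instead
 — carrier pooling is the default because it maximizes group sizes).
The differential-expression ranking is a deliberately light-weight log2
fold change: median-of-ratios size factors (genes containing any zero are
excluded from size-factor estimation only), normalized group means with a
0.5 pseudocount, ranked descending. The downstream contract needs only a
deterministic ranking, so no dispersion shrinkage is attempted. The
ISG-signature ES of that ranking, its permutation p, and the BH
adjustment across the run's candidates follow the enrichment module.

The impact score is w1·z_ES + w2·z_pub + w3·z_FST with (1, 1, 0.5), where
each z is the average rank min-max scaled to [0, 1] (computed over all
filter survivors; |ES| feeds the ES rank). SNPs with adjusted p > 0.05
are eliminated before scoring; the pass flag requires score > 1 and
adjusted p < 0.05. Per-SNP F_ST is site-level by default
(`fst_level="gene"` switches to the host gene's max). The BH family is
all candidate SNPs tested in one run. Per-SNP permutation seeds derive
from a hash of (run seed, SNP id), making the output invariant to input
SNP order. Fewer than two filter survivors is an error (min-max scaling
is undefined), with guidance to relax thresholds.

## Haplotypes

For k ≤ 12 SNPs the 2^k haplotype space is enumerated and frequencies
fitted by EM: each individual's genotype distributes over compatible
haplotype pairs proportional to current frequency products (unordered
pairs, factor 2 for heterozygous pairs), and frequencies re-estimate from
expected counts. The log-likelihood is non-decreasing every iteration
(asserted); convergence is a gain < 1e-8 or 5,000 iterations.
Initialization is uniform over observed-compatible haplotypes; optional
seeded multi-starts escape symmetric fixed points, and near-tied starts
with different frequency vectors raise a `degenerate` flag (a single
double-heterozygote has non-identifiable phase). Individuals missing all
calls are skipped; partially missing sites marginalize over both alleles.
With fully phased (all-homozygous) input EM reduces to direct counting.

LD on two-locus haplotype frequencies (alt alleles as A/B):
D = f(AB) − pA·pB; D′ = |D|/D_max with D_max = min(pA(1−pB), (1−pA)pB)
for D > 0 and min(pA·pB, (1−pA)(1−pB)) otherwise;
r² = D²/(pA(1−pA)pB(1−pB)), which equals the squared Pearson correlation
of the allele indicators. Monomorphic loci are flagged undefined.

Named haplotype groups are configuration, not code. The shipped STING1
rule set orders the four nsSNPs R71H, G230A, R232H, R293Q and codes
alleles by protein residue (0 = the residue of the R232 wild-type
protein): WT = 0000, REF = 0010 (R232H only — the reference genome
carries H232), HAQ = 1101, AQ = 0101; anything else is "other", so the
classification is total. Diplotypes with ≤ 1 heterozygous site phase
unambiguously; more require a haplotype table, which resolves them to the
most probable compatible pair. Missing calls yield "unclassifiable".

## Recurrence scores

A gene counts as a putative copy-number driver in a cancer type iff it is
in a recurrent focal peak with q ≤ 0.25, has G-score ≥ 0.1, is detectably
expressed, and its log(FPKM + 0.001) correlates with copy number at
Pearson p < 0.001 (strict). The pan-cancer overall G-score is the
unweighted sum over passing cancer types. Detectability asks whether the
90th percentile of FPKM reaches 1, i.e. whether at least 10% of specimens
express the gene; percentiles use Weibull plotting positions (R type 6),
under which a gene expressed in exactly the top 10% of samples passes
(the Hazen convention used by numpy's default would fail it). M-score =
mutation index × mutation frequency per cancer; the overall sum gates on
index ≥ 2 by default (`gate_sum=False` sums all cancers and leaves the
gate as a recurrence label only, since the original gating scope is not
fully explicit).

## Stratified association and meta-analysis

Within each ancestry stratum, the phenotype is fit by OLS on a binary
genotype-group indicator plus categorical covariate dummies (cancer
type). OLS replaces a moderated linear model deliberately: variance
shrinkage across genes is irrelevant for a single phenotype. Strata with
fewer than two samples in either group or a singular design are excluded
with a reason, and the meta step's degrees of freedom reflect only
contributing strata. Fisher's method combines the stratum p-values:
X = −2Σ ln p against χ² with 2k degrees of freedom; p = 0 inputs are a
caller error (floor with `P_FLOOR` = 1e-300 first). Local-ancestry
proportions are divided elementwise by global proportions and rescaled to
sum to 1; a positive local proportion over a zero global proportion is
undefined (NaN) and the remaining mass rescales over the defined entries.
When local equals global the result is the uniform vector — all ratios
are 1 — not the local vector itself.

## Synthetic-data generators

One global seed fans out to per-operation substreams
(`SeedSequence.spawn`), so outputs are bit-identical under a fixed seed
and uncoupled across generators.

- **Structured genotypes**: ancestral frequencies uniform on the
  configured MAF interval (default (0.05, 0.5]); deme frequencies Beta
  with mean p and variance F·p(1−p) (shape a = p(1−F)/F,
  b = (1−p)(1−F)/F; F = 0 collapses to a point mass); genotypes
  binomial(2, deme frequency). Defaults (5 populations × 200 samples ×
  2,000 sites) mirror continental-scale cohort proportions at desk scale.
  Optional missing-data injection (sentinel −1) exercises call-rate QC.
- **Expression**: negative-binomial counts, var = μ + αμ² with
  dispersion α = 0.1; gene baselines log-normal (σ = 0.5) around a mean
  of 100 counts; ISG-set genes in carriers get a 2^effect mean shift.
- **MK tables**: per gene, Ds ~ Poisson(mean_ds), Ps ~ Poisson(mean_ps),
  Pn ~ Poisson(ratio_ns·mean_ps), Dn ~ Poisson(ratio_ns·mean_ds/(1−α)),
  so α computed from expected counts equals the configured truth.
  Defaults: 500 genes, means 10, nonsynonymous:synonymous ratio 0.5.
- **Haplotype draws**: each individual receives two i.i.d. haplotypes
  from the configured pool; phase is discarded.

What these emulate is the *statistical structure* the estimators assume
— frequency divergence at a controlled F, a multiplicative genotype
effect on a signature set, count tables with a known adaptive fraction, a
known haplotype pool. They do not emulate linkage structure along the
genome, demography or admixture, batch effects, expression covariance
between genes, or mutation/annotation error; passing tests therefore
demonstrate estimator correctness and calibration under the assumed
models, not robustness to those real-data complications. The
literature-evidence (publication-count) input has no noise model at all
and is consumed as a user-supplied table.

## Monte-Carlo test sizes

Stochastic recovery checks run at the per-draw sizes above and average
over seeded replicates where a single draw's Monte-Carlo SE approaches
the asserted tolerance: pooled-α recovery averages 10 draws of 500 genes
(single-draw SE ≈ 0.035 at α = 0 vs a ±0.03 band), and haplotype-pool
recovery averages 5 draws of 500 individuals (binomial SE ≈ 0.016 on a
0.4 frequency). Null-calibration checks (permutation-p uniformity,
stratified-OLS p uniformity) use 500 replicates and a Kolmogorov-Smirnov
test at the 0.01 level. The end-to-end prioritization checks use 20-SNP
cohorts of 120 cell lines, 400 genes (38 ISG), 500 permutations, and 20
replicates per condition.
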