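# Methods

This note documents the models behind `ssrpop`, the defaults that matter,
the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Data model

An SSR panel is a varieties × loci table of diploid allele-size calls
(bp). Calls are unordered pairs; missing calls are allowed and handled by
pairwise deletion throughout (no imputation), with the gene count behind
every frequency vector retained for audit. Allele frequencies count
allele copies — two per variety, heterozygotes contributing both — which
is the standard convention for co-dominant markers. The genetic map is
purely genetic (chromosome 1–12, cM); no physical coordinates appear
anywhere.

## Synthetic panel generator

The generator emulates an inbred two-subpopulation crop panel — the
setting the pipeline is designed for — using a Balding–Nichols-style
hierarchy:

1. per locus, an allele count k ~ 2 + Poisson(1.9) truncated at 12
   (mean ≈ 3.9 alleles/locus) and an ancestral frequency vector
   π ~ Dirichlet(1, …, 1);
2. subpopulation frequencies p₁, p₂ ~ Dirichlet(π·(1−F)/F), so the
   divergence parameter F ∈ [0, 1) plays the role of the subpopulation
   differentiation; `calibrate_divergence` bisects F until the realized
   between-subpopulation modified Rogers distance matches a target
   (default 0.443, a strong subspecies-level split; F ≈ 0.32 hits it
   under the default configuration);
3. each variety draws one allele per locus from its ancestry-weighted
   frequency vector and duplicates it with probability 0.95 (selfing
   species; the residual heterozygotes exercise the LD module's
   haplotype policy), otherwise draws a second independent allele;
4. admixed varieties mix the two subpopulation frequency vectors with
   an ancestry fraction q ~ Uniform(0.2, 0.8);
5. missing calls are injected at rate 0.02, never emptying a locus.

Defaults mirror the reference panel design: 111/20/19 varieties in
subpopulation 1 / subpopulation 2 / admixed, 274 loci with per-chromosome
counts (23, 25, 24, 22, 21, 22, 21, 25, 23, 24, 23, 21) and mean
exponential inter-locus spacings (7.5 … 5.3 cM). Trait scores are
class-conditional: each of the six morphological scores is
Binomial(4, p) with p = 0.12 for pure subpopulation-1 ancestry
(indica-like, low index) and p = 0.88 for subpopulation 2
(japonica-like), interpolated by ancestry for admixed varieties; the two
measured traits (rachis-internode cm, grain length/width) are drawn
uniformly inside the scoring bin of their intended level, so re-scoring
recovers it.

**What the generator does not emulate.** Loci are exchangeable: allele
frequencies are drawn independently per locus with a single global F, so
there is no chromosome-scale heterogeneity in divergence and no
linkage-generated LD (the only LD is structure-induced, through
subpopulation mixing). Consequences for test interpretation: (i) LD decay
along the map in simulated panels reflects only the nominal false-positive
rate plus mixture LD, so decay tests use constructed curves; (ii)
chromosome-stratified marker subsampling has no real advantage over
random subsampling on simulated panels — their CVs agree to within noise
— whereas on real data, where divergence varies along the genome,
stratification helps. There is also no mutation model (allele sizes are
arbitrary labels spaced 2 bp apart) and no genealogy.

## Population structure

The panel is encoded as a varieties × (locus, allele) matrix of
within-variety frequencies (heterozygote 0.5/0.5, homozygote 1, missing
mean-filled with the panel frequencies and flagged). PCA, PCoA on
pairwise-MRD (Gower double-centring; negative eigenvalues reported, never
used for coordinates), and a spectral embedding of the
correlation-threshold graph (symmetric normalised Laplacian; the trivial
constant eigenvector dropped; isolated varieties kept with self-loops and
a warning) all operate on this geometry, which is why their first axes
agree to |r| ≥ 0.99.

Mixture clustering fits Gaussian mixtures by EM over K = 1…30 and four
covariance families (spherical, diagonal, shared-full, full) and selects
the (K, family) pair maximising BIC in its larger-is-better form
(2·logL − params·log n). Clustering operates on the leading 10 principal
components rather than the raw ~1000-column allele space: with n ≈ 150
varieties the unreduced covariance families are singular, and measured
K-recovery degrades monotonically as dimensions grow past ~10. Two
guards keep model selection honest: fits that fail are skipped with a
log entry, and fits where a component collapses below 2 effective points
(dims+1 for full covariance) are rejected — otherwise the covariance
regularisation floor hands collapsed components unbounded likelihood.

ΔK follows the Evanno second-difference recipe on replicated
log-likelihoods: ΔK = mean over replicates of |L(K+1) − 2L(K) + L(K−1)|
divided by the replicate standard deviation of L(K), with 5 replicates
per K by default; K values with zero replicate spread are flagged
undefined. The replicated series may come from the internal mixture fits
or from an external clustering program's log-likelihood file — the
formula is identical.

Assignment uses either the maximum-probability rule or the 0.80-threshold
rule (inclusive at 0.80; below it a variety joins the admixed group).
Argmax ties break to the lowest-index subgroup with a log record. A known
limitation, inherent to Gaussian mixtures and visible in this package's
own simulations: once clusters are well separated, posterior membership
probabilities saturate at 0/1 even for genuinely intermediate varieties,
so the threshold rule detects far fewer admixed individuals than a
Bayesian admixture model's Q-matrix would. The threshold rule is provided
for compatibility with that workflow, not as a reliable admixture
detector.

Correspondence between two labelings is the agreement fraction under the
best injective matching of the smaller label alphabet into the larger
(Hungarian assignment on the confusion matrix; unmatched labels count as
disagreement; the admixed label is a label like any other).

Neighbor joining uses the standard Saitou–Nei agglomeration; a negative
branch length is clamped to zero with the deficit moved to its sister
branch, preserving the joined pair's path length. Ward clustering of the
six trait scores plus index goes through scipy's linkage.

## Marker-sufficiency resampling

Per subset size (default grid 12 … all loci by 12) and repetition, the
mixture is refitted on the marker subset at the full-panel reference K
and compared to the full-panel max-rule assignment; pairwise MRD on the
subset feeds a per-pair CV (population SD across repetitions / mean,
zero-mean pairs excluded) averaged over pairs. Stratified subsampling
assigns per-chromosome quotas by largest-remainder proportional rounding,
then draws one locus uniformly from each of q contiguous equal-count
segments of the chromosome's map-ordered loci — true stratified sampling,
chosen over a deterministic spacing-greedy pick because repetitions must
vary for a CV to exist. The sufficiency plateau is the smallest grid size
whose mean correspondence reaches 0.95. All repetition seeds derive
deterministically from the master seed.

## Linkage disequilibrium

Varieties project to one haplotype each (homozygote → its allele;
heterozygotes → missing, defensible at 95% homozygosity and avoiding
phase modelling). Alleles observed fewer than twice are pooled into one
class by default to stabilise sparse contingency tables. For the joint
haplotype frequencies x_ij with marginals p_i, q_j:

    D_ij = x_ij − p_i q_j
    D′   = Σ_ij p_i q_j |D_ij| / Dmax_ij
    r²   = Σ_ij p_i q_j D_ij² / (p_i(1−p_i) q_j(1−q_j))

which for biallelic pairs reduces exactly to the classical squared allele
correlation. Significance: two-sided Fisher exact test for 2×2 tables;
otherwise a seeded Monte-Carlo permutation test of one locus's call
vector (default 10,000 shuffles, table chi-square statistic, add-one
correction so p > 0). Decay uses the 75th percentile
(linear-interpolation quantile) of inter-chromosomal r² as threshold and
a 5-cM sliding window at 1-cM steps over linked pairs; the decay distance
is the left edge of the first window that falls below the threshold and
stays below it (0 if even the first window is below; reported as beyond
the map extent when no window qualifies). LD blocks are maximal runs of
≥ 2 map-adjacent loci (configurable) whose every consecutive pair is
significant; the group-level mean block length is reported both ways the
twelve per-chromosome means can be averaged (blockless chromosomes
excluded, or included as zero), since the two conventions differ.

## Problem sizes used by the test suite

The suite's heavier checks run at sizes chosen to keep a single-CPU run
comfortable while preserving the statistical signal: parameter-recovery
experiments use 100 seeded panels at the full 150 × 274 design with
K ∈ 1…6; resampling curves use 25 repetitions on a 12…274-by-24 grid;
LD behaviour checks use 60-locus panels with 400 permutation shuffles
(Monte-Carlo permutation p-values are valid at any shuffle count; more
shuffles only refine resolution). Bootstrap standard errors default to
1000 replicates in production and use 5–200 in tests.

## Known limitations

- The threshold-rule admixed group under Gaussian posteriors is
  conservative to the point of near-emptiness on well-separated panels
  (see above).
- BIC model selection on panels containing a spread-out admixed fraction
  can prefer K = 3 (the intermediate varieties form a genuine bridge
  cluster); the ΔK statistic is more stable for the two-subgroup signal.
- Gst and the diversity scan assume the panel-wide allele list is shared
  across groups (guaranteed when tables come from `allele_frequencies`).
- The permutation LD test conditions on the observed margins; extremely
  sparse tables (gene counts < ~10) yield coarse p-values.
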