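# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The NAM design and the BC1S3 simulator

The target design is a nested association mapping population: `n_families`
wild donors each crossed to one shared elite recurrent parent; the F1 is
backcrossed once to the recurrent parent (BC1) and selfed for three
generations by single-seed descent (BC1S3).  Each line is an independent
lineage from its own BC1 plant.  Under this scheme the single-locus
genotype distribution is exactly

    P(het) = (1/2)·(1/2)^3 = 1/16 = 6.25%,
    P(hom donor) = 7/32,   P(hom recurrent) = 23/32,

and the expected donor genome proportion is 25%.  These closed forms are
re-derived in the tests by brute-force enumeration of the crossing-scheme
Markov chain and checked against the simulator empirically.

**Meiosis model.** Crossovers follow Haldane's model (no interference) on
the cM map.  Rather than placing Poisson-distributed crossover positions
explicitly, the simulator draws the gamete's founder-origin process
directly at the marker positions: along a chromosome this process is a
two-state Markov chain whose switch probability between adjacent markers at
distance d cM is the Haldane recombination fraction ½(1 − e^(−2d/100)).
Under no interference the two formulations have identical marginals at the
markers; the Markov form vectorises over lines.  Chromosomes assort
independently (equivalently, the switch probability at a chromosome start
is ½, which also randomises the starting haplotype).  A zero-length
chromosome is legal and yields complete linkage.

**Founders.** The recurrent parent carries the reference allele at every
SNP.  Donors draw the alternative allele independently per SNP with
probability `donor_polymorphism_rate` (default 0.5).  Real wild accessions
share ancestry and LD; no haplotype model is imposed because downstream
inference never uses donor haplotype sharing.  Selection during line
development is not modelled.

**Phenotypes.** A planted-QTL phenotype is

    g_i = Σ_k effect_k · multiplier_k[family_i] · dosage_ik,
    y_i = g_i + e_i,   e_i ~ N(0, σ²_e),

with σ²_e set from the realised sample Var(g) so that
Var(g)/(Var(g)+σ²_e) equals the target h² exactly.  With the default
metabolite-like link the standardised sum is exponentiated
(`exp(y/sd(y))`), producing positive right-skewed values so the Box-Cox
stage is non-trivial; h² then refers to the latent (log) scale.  The
generator emits the ground truth (genetic values, noise variance, planted
effects) for recovery tests.  Missingness is injected completely at
random; replicated control genotypes (default 17, emulating repeated elite
check lines of a field trial) share a genotype-specific mean per
metabolite for repeatability estimation.

**Desk-scale defaults.** 25 families × 52 lines = 1300 lines, 2000 SNPs on
7 chromosomes of 150 cM (1 Mbp/cM, evenly spaced).  These dimensions keep
every full-pipeline computation on one CPU core in minutes while retaining
the family structure, marker density and linkage decay that drive the
method's behaviour.

**What the generator does not emulate.** Field-trial spatial structure,
genotyping error, segregation distortion/selection, donor LD and GC-MS
measurement artefacts are all absent.  Passing tests therefore demonstrate
the correctness and calibration of the *statistical machinery* under the
stated genetic model, not robustness to those real-data complications.

## Genotype processing

QC keeps a marker iff (i) at least one family shows ≥ 2 distinct
non-missing call states, (ii) the failure rate over all lines is strictly
below 0.10, and (iii) the heterozygous rate among non-missing calls is
strictly below 0.125.  Thresholds are applied as strict inequalities as
printed; the failure rate is computed as missing/total so that a marker at
exactly 10% missing fails deterministically.  The heterozygous-rate
denominator is called genotypes only — a rate of a call state is naturally
conditioned on the marker having been called.

IBS coding maps calls to 0/1/2.  The monomorphic-family recode is applied
for *any* within-family monomorphism (not only the all-elite state, which
is the case spelled out for two families in the field's usage): an allele
that does not segregate within a family is indistinguishable from the
recurrent-parent state for mapping purposes, so all lines of that family
are set to 0 at that SNP.  A family with all calls missing at a SNP counts
as monomorphic (conservative).  Recode decisions are kept on the matrix
(`IBSMatrix.recoded`) for inspection.

Mean imputation uses population-wide column means by default (a per-family
option exists); pre-imputation integer states are preserved because the
dominance kernel and family-segregation tests must not see imputed
fractional scores.

## Phenotype processing

Metabolite columns with missing fraction strictly greater than 0.10 are
dropped (a column at exactly 10% is kept); remaining missing values are
replaced by the column minimum *before* transformation.  Box-Cox λ is
selected on the fixed grid −3 … 3 by 0.25 by maximising the standard
profile log-likelihood (λ = 0 → log); exact ties break toward the λ
closest to 1 (least distortion).  Values that are non-positive (possible
only in raw-data mode) are shifted by 1 − min before transforming.  Note
that λ is only identified when the coefficient of variation is
substantial; for near-constant positive data the profile likelihood is
nearly flat and the grid argmax is arbitrary.  Correlations use
pairwise-complete observations with two-sided t-test p-values and
significance marks at 0.05 / 0.01 / 0.0001.

## Variance components

Kernels from the imputed IBS matrix Z (lines × markers):

* additive: A = Z_c Z_cᵀ scaled to mean diagonal 1 (Z_c column-centred) —
  the VanRaden-style genomic relationship on IBS scores;
* dominance: the same construction on centred heterozygosity indicators
  (1 iff the pre-imputation state is heterozygous); a fully inbred panel
  gives D = 0;
* epistasis: the Hadamard square A∘A, rescaled to mean diagonal 1
  (additive×additive).

All three are Gram or Hadamard-of-Gram matrices, hence PSD (Schur product
theorem); tests verify min eigenvalue ≥ −1e−8.

`GenomicHeritability` fits y = μ + g_A + g_D + g_I + e by REML using
average-information updates with EM-stabilised first steps (3 by default),
non-negativity constraints on all components (a component pinned at zero
with negative gradient is dropped from the update), step-halving on the
restricted likelihood, and convergence at |Δll| < 1e−6.  Zero kernels are
excluded automatically.  The reported h²_SNP is computed exactly from the
stored components.  The optimiser is cross-checked in the tests against a
brute-force two-dimensional grid search over the same restricted
likelihood on an additive-only instance.

A caution from the recovery experiments built into the test suite: h²
recovery is calibrated for *polygenic* architectures with effects of both
signs.  Architectures in which all wild alleles act in the same direction
couple the genetic value to genome-wide donor dosage and family structure,
and kernel-based REML then attributes part of that variance differently —
a model-misspecification effect, not an optimiser failure.

Repeatability uses the one-way random-effects ANOVA expected mean squares;
unbalanced designs use n₀ = (N − Σnᵢ²/N)/(g − 1) as the effective
replication number r.  V_G is truncated at 0 and rep clamped to [0, 1];
V_R = 0 with distinct genotype means gives rep = 1 by convention.

## Stepwise GWAS and cross-validation

The selector starts from the intercept-only model.  Forward: the candidate
whose addition has the smallest marginal-F p-value enters if p < 0.001.
Backward: after every entry, elimination runs to exhaustion, removing the
term with the largest partial (type-II) p-value while p ≥ 0.001, all
coefficients refit jointly after each change.  Ties on p-values break
toward the earliest candidate column; callers order columns by
(chromosome, bp), making the tie-break map order.  A rank guard skips any
candidate whose residual against the current design has collapsed
(relative squared norm < 1e−10), so the design stays full rank and exact
duplicates resolve to the earliest column.  The default model-size cap is
min(50, n/10) and guarantees termination together with a sweep cap.

Implementation: forward scans residualise all candidates against the
selected set progressively (one rank-1 update per entry), so a scan is a
single matrix–vector product; the F statistic from the residual
correlation is algebraically identical to the marginal F-test of the new
term in the joint refit.  The tests hold the selector to *exact*
agreement — same SNPs, same order, same coefficients — with a naive
reference that refits the joint model for every candidate at every step.

Cross-validation is stratified by family: within each family and
repetition, shuffled lines are dealt cyclically into k folds (sizes differ
by ≤ 1; a 52-line family at k = 5 gives 11,11,10,10,10).  Defaults k = 5,
20 repetitions → 100 runs; every line is predicted exactly 20 times.
Prediction ability is the squared Pearson correlation on the held-out
fold, defined as 0 (flagged) when the model is empty or predictions are
constant.

The detection-rate threshold re-runs the entire cross-validation on
shuffled matrices: phenotype rows are permuted as whole records against
the genotypes (preserving inter-metabolite correlation), default 3
shuffles over the analysed phenotype set.  Per-SNP DR values are pooled
over metabolites and shuffles, and the threshold is the smallest integer t
such that at least 99.99% of pooled DRs are strictly below t.  An all-zero
pool yields t = 1, and raising the percentile can only raise t.  Null DR
distributions are heavy-tailed — a SNP that happens to correlate with the
fixed shuffled phenotype recurs across overlapping training sets — which
is exactly why the threshold must be calibrated empirically rather than
derived from per-test α.

By default only metabolites with mean prediction ability r² > 0.2 are
screened for mQTL reporting (configurable).

## mQTL regions, explained variance, family effects

Threshold-exceeding SNPs on one chromosome merge into a region when
consecutive significant SNPs are ≤ 5 Mbp apart (configurable); regions are
numbered per chromosome with barley-style ids (`2H-1`, optional sampling-
date suffix).  The merge rule is positional because no grouping rule is
canonical; 5 Mbp on the desk map corresponds to 5 cM.  The peak SNP has
maximal DR, ties broken by |mean β̂| then map order.  Region explained
variance is the R² of the joint OLS of the phenotype on all member SNPs
over the whole panel, with QR-based pruning of collinear members (flagged,
never fatal).

Family effects use the cumulation reading: within each CV run, the
family's effect for a region is Σ 2β̂ over member SNPs that entered that
run's final model *and* segregate within the family (≥ 2 distinct
pre-imputation IBS states after recoding); the final estimate is the mean
over all runs, runs without any such SNP contributing 0.  The factor 2 is
the homozygous-wild vs elite contrast (two IBS units).  A family where no
member SNP segregates gets exactly 0 by construction.  Because one shared
coefficient is fitted per SNP, opposite-sign family effects can only arise
from different (family-private) member SNPs, not from a single SNP shared
by both families — the recovery tests are built accordingly.

## Reproducibility and problem sizes

All randomness flows from integer seeds through `numpy` generators;
identical configuration + seed reproduces byte-identical report bundles
(fixed float formatting, sorted JSON keys, content-hash in the metadata).
The acceptance suite runs the simulator checks at 2000 lines × 1200 loci,
stepwise/naive equivalence on 50 instances of n = 60 × 20 SNPs, the null
calibration at 1300 lines × 1000 SNPs × 100 CV runs × 20 trials, QTL
recovery at 1300 × 2000 with 10 seeds, heritability recovery with 20
replicates per level at 1300 × 2000, and the determinism check on a
reduced 200-line configuration (bit-level reproducibility is scale-free).
These sizes were chosen so the full suite completes on a single CPU core
in well under half an hour.

## Limitations

* No mixed-model (kinship/PCA) correction in the GWAS stage: the method
  relies on multi-locus selection and family-stratified CV, so directional
  polygenic architectures can inflate detection of structure-tagging SNPs;
  the permutation threshold (which destroys phenotype–structure links) is
  only a partial guard.
* The cumulation estimate inherits the selection-conditioned bias of the
  per-run coefficients (winner's curse on |β̂|).
* REML components are point estimates; no standard errors are reported for
  h²_SNP.
* The simulator's idealisations listed above (no selection, no genotyping
  error, independent donors).
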