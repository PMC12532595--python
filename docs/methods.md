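# Methods

This note documents the models implemented in `bagwas`, the assumptions of
the synthetic-data generator, the numerical choices that required a
decision, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Brain age and BAG

Brain age is estimated by k-fold cross-prediction with repeats: per repeat a
fresh seeded fold assignment is drawn; within each fold a PCA transform and
every learner are fitted on the training folds only and applied to the
held-out fold, so each (individual, repeat) cell of the prediction tensor is
produced by models that never saw that individual. Fold sizes are as equal
as possible, with the remainder distributed to the first folds.

Stacking is a linear meta-model (ordinary least squares with intercept)
fitted on nested out-of-fold predictions — first across learners within a
tissue class, then across the two tissue-level predictions for the combined
estimate — and repeat-level estimates are averaged at the end. The paper
family this pipeline belongs to does not pin down the stacking learner, so
OLS was chosen for determinism and zero extra hyperparameters; a single
learner passes through with meta-weight one, and a combined estimate
requires at least two tissues. Repeat-averaging is applied after stacking at
every level.

Desk-scale defaults are 50 principal components and 5 repeats (full-scale
values such as 500 components and 100 repeats remain configurable), and the
default learner roster is a ridge linear model plus gradient-boosted trees —
cheap stand-ins spanning the linear/nonlinear split of the heavier
RVM/boosted ensembles used in production pipelines. Learners are pluggable:
anything with sklearn fit/predict semantics.

`BAG = predicted age − chronological age`. Because predictions regress
toward the training mean, raw BAG is negatively correlated with age
(regression dilution); the correction used throughout is covariate
adjustment with age and age² (plus sex, scanner site, total intracranial
volume, genotyping array and genetic PCs), either by residualization (for
reliability and descriptive statistics) or by including the covariates in
the association model — the two are equivalent for the dosage t-statistic by
Frisch–Waugh, and a test asserts that identity.

Metrics: Pearson r; R² = 1 − SS_res/SS_tot computed against the identity
(no refit), which is **not** r² and can be negative for a miscalibrated
predictor; MAE in years; ICC(C,1), the two-way mixed-effects consistency
single-measurement intraclass correlation, computed from the classical
ANOVA decomposition (cross-checked against pingouin in the tests).

## Association and meta-analysis

The GWAS is per-variant OLS of the phenotype on allele dosage plus
covariates and intercept, implemented by QR residualization (numerically
exact, vectorized over variants; df = n − k_cov − 2). Dosages stay on their
ploidy scale (0–2 diploid/X/pseudoautosomal, 0–1 for Y). Monomorphic
variants yield an NA row with a reason code.

Meta-analysis is fixed-effects IVW (β = Σwβ/Σw, w = 1/se²) with alleles
harmonized by (chrom, pos): a swap flips β and frequency; strand flips are
resolved through complements; palindromic variants are resolved by allele
frequency only when both frequencies are informative (|f − 0.5| > 0.2),
otherwise dropped. Variants with meta N below 67% of the 90th percentile of
N, or Cochran-Q heterogeneity p < 1e-6, are removed into an exclusion
manifest.

Independent signals come from stepwise conditional analysis implemented as
exact joint regression on the individual-level synthetic panel (a
summary+reference-LD approximation is unnecessary at this scale): repeat
{compute each candidate's p conditional on the selected variants within a
10,000-kb window, skipping candidates with r² > 0.9 against any selected
variant; add the best if conditional p < 5e-8}. Subsidiary signals whose
conditional p exceeds their marginal p by more than two orders of magnitude
are discarded. A consequence worth knowing: under that rule a same-sign
secondary in LD (r² ≈ 0.3) with genome-wide significance is *always*
discarded, because the marginal p absorbs both effects; genuinely
recoverable secondary signals are masked (opposite-sign) pairs, and the test
suite covers both situations. Index variants across traits are greedily
clumped by ascending p (r² < 0.1, 10,000-kb window) into loci; a locus is
novel unless a known-list variant clumps with one of its members under the
same parameters.

## Replication statistics and winner's curse

Sign-concordance and nominal-replication counts are tested with one-sided
upper-tail binomials (p₀ = 0.5 and p₀ = α = 0.05 respectively); "one-tailed
nominal significance" means the one-sided replication p in the discovery
direction is below 0.05.

Winner's-curse correction is the conditional-likelihood MLE of the true
noncentrality given that |z| exceeded the variant's own two-sided selection
threshold c (5e-8 genome-wide, 1e-6 suggestive), solved by bounded 1-D
minimization of the truncated-normal negative log-likelihood. Replication
power uses the corrected standardized β with se_rep = 1/√(2·maf·(1−maf)·n_rep)
for a unit-variance phenotype and one-tailed level α:
power = 1 − Φ(z_α − |β_corr|/se_rep); expected replications are the sum of
per-variant powers (covariate-explained variance is ignored — conservative).

A documented limitation: the conditional MLE overcorrects when power is
high (for z well above c the shrinkage exceeds the actual selection bias),
so "corrected bias < raw bias" is a property of the marginal-power regime
the correction targets. The validation experiment therefore draws true
noncentralities uniformly in [4, 5] (discovery power roughly 10–35% at
genome-wide α), simulates discovery z unconditionally, keeps ascertained
loci exactly as selection operates, and compares the estimator bias
|E(ẑ − μ)| of corrected versus raw estimates; sign flips never occur and
|ẑ| shrinks strictly.

## Fine-mapping, SMR and gene prioritization

Fine-mapping is a deliberate single-causal stand-in: the Wakefield
approximate Bayes factor ABF = √(1−r)·exp(z²r/2) with r = W/(W + se²) and
prior effect SD 0.3 years (matching the observed per-allele scale of BAG
effects, ~0.1–0.5 years), computed in log space. PIPs are ABFs normalized
over the locus (summing to one by construction) and the 95% credible set is
the minimal PIP-descending prefix. A set is assigned to a locus iff it holds
a genome-wide-significant credible variant in strong LD (r² > 0.8) within
3,000 kb of the index variant. Each index variant is fine-mapped separately;
secondary conditional signals do not get their own sets.

SMR: β_xy = β_zy/β_zx of the top cis-instrument (smallest eQTL p, required
< 5e-8), se by the delta method, p from the normal. HEIDI uses secondary
instruments with 0.05 < r² < 0.9 against the top (at most 20, by eQTL p),
forms d_i = b_i − b_top with an LD-aware first-order covariance and tests
the quadratic form against χ² with m − 1 df; small p indicates linkage
rather than mediation/pleiotropy. Retention: FDR < 0.05 within probe type
(eQTL and sQTL corrected separately) and HEIDI p > 0.01.

Variant-to-gene mapping follows positional precedence exonic > splice
region (±2 bp) > UTR > intronic > up/downstream (≤1 kb) > intergenic, with
intergenic variants assigned to the nearest gene (ties to the smaller start
coordinate). Seven nomination streams per locus: (1) credible-variant PIP
mass per mapped gene, C_i; (2) max CADD Phred among nonsynonymous credible
variants; (3) SMR eQTL and (4) sQTL by p; (5) single-tissue eQTL lookup over
the index variant and strong-LD (r² > 0.8) neighbors, by count of
significant tissues; (6) multi-tissue eQTL after the filters ≥10 tissues,
m ≥ 0.9 in ≥50% of tissues, RE2 p < 5e-8, by tissue count; (7) the top
three PoPS genes within 500 kb. Ranks are competition ranks (ties share the
best rank; the next rank is skipped). The priority score is
P_i = C_i + Σ_{j=1..6} 2(n_j + 1 − R_ij)/(n_j(n_j + 1)) over the six ranked
streams — each contributes exactly one point across its ranks — and the
winner is the argmax, ties broken by proximity to the index variant.

## Gene-based tests and GO enrichment

The gene test aggregates T = Σz² over variants inside gene bounds (zero
flank). Under LD the null is Σλ_j·χ²₁ with λ the eigenvalues of the variant
LD correlation matrix; the tail is approximated by the two-moment
Satterthwaite match (scale Σλ²/Σλ, df (Σλ)²/Σλ²), which the tests hold
within 1.5× of a 100,000-draw Monte-Carlo oracle near p = 0.01. Gene FDR is
BH; significant genes are clumped top-p-first within 3,000 kb.

GO enrichment tests each term for lower-than-expected member p-value ranks
with a one-sided normal rank-sum statistic (p-values are continuous, so no
tie correction; the same statistic is used for observed and permuted data so
the permutation comparison is exact). The FWER null permutes gene labels and
records the minimum term p across all three aspects jointly; per-term joint
FWER is the fraction of permutations at least as extreme. Terms containing
every analyzed gene (aspect roots) have a degenerate statistic and are
assigned p = 1. elim refinement processes specific terms before general
ones (topological order on the is_a DAG): a term significant at joint
FWER < 0.05 has its genes removed from all ancestors, which are re-tested
against the same permutation null. Contributing loci per term count
FDR-significant member genes after 3,000-kb positional clumping. Default
permutation count is 1,000 (≥100 recommended; <10 is an error).

## Mendelian randomization and polygenic scores

GSMR: instruments are exposure variants at p < 5e-8 surviving r² < 0.001
clumping in a 10,000-kb window; instrument effects on continuous exposures
are standardized per SD as β_sd = z/√(2p(1−p)(n + z²)). Per-instrument
ratios b_i = β_zy/β_zx are combined by GLS. Four numerical choices, each
motivated by a measured failure of the naive alternative (see the tests):
ratio variances use a two-pass plug-in (a first pass with outcome-only
weights yields the pooled estimate that enters the exposure-error term), so
weights do not share noise with the individual ratios; a second-order
weak-instrument term (1 + 3(se_zx/β_zx)²) inflates the ratio variance;
post-clumping off-diagonal LD below |r| = 0.05 is zeroed in the GLS
covariance (it is reference-panel sampling noise); and HEIDI-outlier
trimming (per-instrument p < 0.01 against the leave-one-out GLS estimate)
only runs when a global Cochran-Q test over the ratios rejects homogeneity
at 0.05 — trimming a homogeneous set distorts the estimator's sampling
distribution. Reverse MR swaps the roles of the two summary tables. In a
forward-only simulated world the outcome's genetic effects are diluted
mediated copies of the exposure instruments, so reverse selection at
genome-wide significance typically finds too few instruments — the expected
null signature, asserted in the tests.

C+P PGS: training summary statistics are p-informed clumped (r² < 0.1,
500-kb window, target panel as LD reference); for each of the ten default
thresholds (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0) the
score is Σβ·dosage over retained variants below the threshold, so variant
sets nest across thresholds by construction. Evaluation is the partial
correlation of score and phenotype given the covariates (identical to the
correlation of covariate-residualized score and phenotype); training/target
identifier sets, when supplied, must be disjoint.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Genotypes.** Per LD block, each haplotype carries a latent Gaussian AR(1)
series (parameter `block_rho`, default 0.7, block size 20); the allele is
present where the latent value is below the quantile of the variant's
allele frequency (drawn uniformly from `maf_range`, default 0.05–0.5), and
haplotypes sum to Hardy–Weinberg dosages. Blocks are separated by 20-Mb
gaps so no 10-Mb analysis window spans blocks; between-block correlation is
zero in expectation. Ploidy classes chrX/chrY/chrXY exercise the dosage
scales; INFO is 1.0 throughout (imputation is not modeled). Coordinates are
1-based inclusive internally; BED is written 0-based half-open, GFF3
1-based.

**Phenotype.** bag_true = centered G·β scaled so the genetic variance is
`h2_bag` of a total BAG variance of `bag_sd`² (default 3² years², the
scale of real BAG distributions) + covariate effects + Gaussian noise. The
covariate effects are free parameters the source material does not
constrain, set once to small realistic values: site effects ~N(0, 0.3 yr),
a 0.2-yr sex effect, 0.002 yr per TIV unit (~0.24 yr per TIV SD).

**Features.** Each tissue's feature matrix is w·(age + bag_true) + nuisance
latents + Gaussian noise (default 2 yr-equivalent SD); with zero noise a
linear readout reproduces age + BAG exactly, which pins the information
content of the features. Ages are uniform on 45.2–81.9 years.

**Retest.** The retest BAG is λ·bag_true + √(1−λ²)·fresh noise with
λ = `retest_icc_target` (default 0.90): for two equal-variance sessions the
consistency ICC equals their correlation, so λ is the closed-form choice.

**Omics fixtures.** Two non-overlapping genes per block; a designated
subset of causal variants is "mediated": the causal eQTL effect is
β_zx = β_bag/β_xy (β_xy default 0.4), and every LD neighbor inherits the
projected marginal effects, so the implied instrument ratio equals the
planted β_xy exactly in the noise-free projection. Multi-tissue records are
generated on both sides of every lookup filter boundary (9 vs 10 tissues;
m ≥ 0.9 in 40% vs exactly 50% of tissues) with the expected outcomes
recorded in the manifest. CADD marks mediated causals nonsynonymous with
high Phred scores; PoPS boosts the designated gene; the GO DAG has one root
per aspect and two levels below it.

**Exposure GWAS.** One instrument per independent block; true effects are
sized at noncentrality ≈ 8 + |N(0,1)| for the stated sample size (default
20,000), so essentially all planted instruments clear 5e-8; exposure and
outcome errors are drawn independently (the two-sample contract, assertable
on the stored error streams); the outcome effect is b_xy_true·γ plus
optional pleiotropy.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: realistic MRI voxel geometry and spatial
autocorrelation, imputation uncertainty, population stratification and
relatedness, non-additive genetic effects, real LD beyond block-AR(1)
decay, and linkage between blocks. Calibration and recovery results here
show the estimators are correct under their stated assumptions, not that
those assumptions hold in any particular cohort.

## Problem sizes in the validation experiments

Chosen once as desk-scale conditions with acceptable Monte-Carlo error:
GWAS type-I error on 4,000 independent null variants (n = 1,000); ABF
coverage over 500 loci (25 variants, n = 1,500, causal z ≈ 6); GO null FWER
over 400 replicate datasets with 400 permutations each; power formula vs
10,000 Monte-Carlo replications at analytic power ≈ 0.85; GSMR over 400
replicate summary simulations (30 instruments, n = 20,000 per sample);
winner's curse over 1,000 ascertained loci; heritability recovery at
n = 4,000; ICC recovery on 400 retest pairs; gene-prioritization recovery
over 100 constructed loci; tensor cardinality at 100 repeats on a
60-individual toy.

## Known limitations

* The single-causal ABF model ignores multiple causal variants per locus;
  loci with secondary signals inherit the assumption's biases by design.
* The conditional-MLE winner's-curse correction overcorrects at high power
  (see above).
* HEIDI's first-order covariance approximates cross-instrument correlation
  through LD with the top instrument; exact only relative to the top.
* The GO rank-sum statistic uses the normal approximation for all term
  sizes; very small terms (<5 genes) have coarse p-values, which the
  permutation FWER absorbs but the raw p column inherits.
* Binary outcomes are out of scope throughout (continuous exposures and
  phenotypes only).
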