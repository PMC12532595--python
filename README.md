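# bagwas

A toolkit for the genetics of the **brain age gap (BAG)** — the difference
between an individual's machine-learning-predicted brain age and their
chronological age, `BAG = Â_brain − A_chron`, in years. A positive gap reads
as accelerated brain aging and is heritable, so it can be dissected with the
standard population-genetics machinery. `bagwas` implements that full
pipeline as a tested, reusable library:

* **Age estimation** (`bagwas.brainage`): k-fold cross-prediction with
  repeats over PCA-reduced imaging features, an ensemble of learners stacked
  within and across tissue classes (gray/white matter) by linear meta-models
  fitted on nested out-of-fold predictions; BAG with covariate adjustment for
  the regression-dilution age dependence; r, R² = 1 − SS_res/SS_tot, MAE and
  test–retest ICC(C,1).
* **Association** (`bagwas.assoc`): additive dosage GWAS with covariates
  (exact Frisch–Waugh residualization), fixed-effects inverse-variance
  meta-analysis with sample-size and Cochran-Q heterogeneity filters,
  stepwise conditional selection of independent index variants (10,000-kb
  window, collinearity 0.9, two-orders-of-magnitude subsidiary rule), and
  cross-trait LD clumping (r² < 0.1) into loci with novelty flags.
* **Scalar statistics** (`bagwas.stats`): r from a regression z-statistic,
  r = sign(β)·√(z²/(z² + n − k − 2)); sex-difference z-tests; one-sided
  binomial sign/replication tests; winner's-curse correction by a
  conditional-likelihood truncated-normal MLE with analytic replication
  power; Fisher exact annotation enrichment; Bonferroni/BH adjustment.
* **Post-GWAS** (`bagwas.postgwas`): single-causal Wakefield
  approximate-Bayes-factor fine-mapping (`ABF = √(1−r)·exp(z²r/2)`,
  r = W/(W+se²)), 95% credible sets with PIP normalization; SMR mediation
  tests `β_xy = β_zy/β_zx` with delta-method SEs and the HEIDI linkage
  heterogeneity test; seven-stream gene nomination (credible-variant
  annotation mass, CADD, SMR eQTL/sQTL, single-/multi-tissue eQTL lookup,
  PoPS top-3 within 500 kb) and the composite priority score
  `P_i = C_i + Σ_j 2(n_j + 1 − R_ij)/(n_j(n_j + 1))`.
* **Gene sets** (`bagwas.geneset`): sum-of-χ² gene-based tests with
  LD-eigenvalue (Satterthwaite) nulls and 3,000-kb clumping; GO enrichment by
  one-sided rank-sum tests with permutation FWER joined across the three GO
  aspects and elim refinement of nested terms.
* **MR and PGS** (`bagwas.mrpgs`): GSMR-style multi-instrument Mendelian
  randomization (per-SD standardized instruments, GLS combination,
  HEIDI-outlier removal, forward/reverse) and clumping + p-thresholding
  polygenic scores evaluated by partial correlation.
* **Synthetic cohorts** (`bagwas.syndata`): a fully seeded generator for
  LD-block dosage genotypes, a BAG phenotype with planted causal variants at
  configurable heritability, imaging features whose noiseless linear readout
  is exactly age + BAG, retest replicates at a target ICC,
  mediation-consistent eQTL fixtures, CADD/PoPS-like score tables, a small GO
  DAG and two-sample exposure GWAS with planted causal effects — so every
  stage is testable end to end without restricted data.

## Worked example

```python
import numpy as np
from sklearn.linear_model import Ridge
import bagwas as bw

cfg = bw.SimConfig(n_individuals=2000, n_variants=200, ld_block_size=20,
                   block_rho=0.7, n_causal=5, h2_bag=0.25, seed=42)
panel = bw.simulate_genotypes(cfg)
cohort, arch = bw.simulate_cohort(panel, cfg)

plan = bw.CrossPredictionPlan(n_folds=10, n_repeats=2, n_components=20,
                              learners=[("ridge", Ridge())], seed=0)
oof = bw.crosspredict_ensemble({"gm": cohort.features_gm,
                                "wm": cohort.features_wm}, cohort.age, plan)
est = bw.stack_predictions(oof, cohort.age, plan)
m = bw.model_metrics(est.pred_combined, cohort.age)

ss = bw.gwas_linear(panel, cohort.bag_true, cohort.covariates())
sel = bw.stepwise_conditional(ss, panel, cohort.bag_true, cohort.covariates())
loci = bw.clump_and_flag(sel.assign(trait="bag"), panel)

lead = sel.iloc[0]
block = panel.block_index[panel.index_of(lead["id"])]
locus_ss = ss[np.asarray(panel.block_index) == block].reset_index(drop=True)
gi = panel.index_of(lead["id"])
ld = np.array([panel.ld_r(gi, panel.index_of(v)) for v in locus_ss["id"]])
cs = bw.abf_credible_set(locus_ss, lead["id"], ld_to_index=ld)

xg = bw.simulate_exposure_gwas(panel, cfg, n_instruments=10, b_xy_true=0.5)
mr = bw.gsmr(xg.exposure, xg.outcome, panel)
```

prints (via the obvious `print` statements):

```
combined age prediction: r = 0.960, R2 = 0.922, MAE = 2.32 years
adjusted BAG: sd = 2.77 years
independent signals: 3, loci: 3
   id      beta       se            p
rs124 -1.728453 0.103222 5.656575e-59
rs183  1.450875 0.102339 1.568462e-43
 rs52  1.655867 0.216215 2.920312e-14
95% credible set at rs124: 1 variants, top PIP = 1.00, assigned = True
GSMR: b_xy = 0.447 (se 0.041, p = 3.03e-27), 10 instruments
```

Reading the numbers: the stacked ensemble predicts chronological age with
r = 0.96 and a mean absolute error of 2.3 years on this synthetic cohort
(noise-limited; real cohorts land near MAE 3). Three of the five planted
causal variants are strong enough to clear genome-wide significance and
survive conditional analysis as independent loci. The lead locus fine-maps
to a single-variant 95% credible set, and two-sample MR on the simulated
exposure recovers the planted causal effect of 0.5 within two standard
errors.

A thin CLI mirrors the stages (`bagwas simulate`, `gwas`, `meta`,
`cojo-select`, `clump`, `finemap`, `repstats`, `enrich-fisher`, `adjust`,
`genetest`, `goenrich`, `mr`, `pgs`, `brainage`); run `bagwas --help`.

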