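"""Seeded end-to-end validation experiments.

Each function regenerates its inputs from scratch through the synthetic
cohort generator (or closed-form summary-level simulation), runs the
corresponding pipeline stage and measures calibration or parameter
recovery.  These are the experiments behind ``scripts/acceptance.py`` and
the acceptance test suite; problem sizes are chosen to finish on one CPU in
minutes and are documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import (
    CrossPredictionPlan,
    SimConfig,
    abf_credible_set,
    crosspredict_ensemble,
    go_enrichment,
    gsmr,
    gwas_linear,
    icc_c1,
    nominate_genes,
    priority_score,
    replication_tests,
    simulate_cohort,
    simulate_exposure_gwas,
    simulate_genotypes,
    simulate_omics_fixtures,
    smr_heidi,
    smr_table,
    stack_predictions,
    winners_curse_z,
)
from .brainage import StackedAgeEstimate, OofPredictions


def _records(n: int, concordant: int, replicated: int) -> pd.DataFrame:
    """Replication records with the requested concordance/replication counts.

    Replicated records must be concordant (a one-tailed replication p in the
    discovery direction below 0.05 implies a matching sign)."""
    assert replicated <= concordant <= n
    beta_disc = np.ones(n)
    beta_rep = np.where(np.arange(n) < concordant, 1.0, -1.0)
    p_rep = np.where(np.arange(n) < replicated, 1e-3, 0.9)
    return pd.DataFrame({"beta_disc": beta_disc, "beta_rep": beta_rep, "p_rep": p_rep})


def replication_binomials() -> dict[str, float]:
    """One-sided binomial tails for the four headline replication counts:
    25/25 and 36/45 sign-concordant (p0 = 0.5); 18/25 and 24/45 nominally
    replicated (p0 = 0.05)."""
    r25 = replication_tests(_records(25, 25, 18))
    r45 = replication_tests(_records(45, 36, 24))
    return {
        "concordance_p_25of25": r25["p_sign"],
        "replication_p_18of25": r25["p_binom"],
        "concordance_p_36of45": r45["p_sign"],
        "replication_p_24of45": r45["p_binom"],
    }


def gwas_type1(seed: int, n_variants: int = 4000, n_individuals: int = 1000,
               alpha: float = 0.05) -> dict:
    """Type-I error of the dosage GWAS on a permuted (null) phenotype."""
    cfg = SimConfig(n_individuals=n_individuals, n_variants=n_variants,
                    ld_block_size=1, block_rho=0.0, n_causal=0, h2_bag=0.0,
                    seed=seed)
    panel = simulate_genotypes(cfg)
    cohort, _ = simulate_cohort(panel, cfg)
    rng = np.random.default_rng(seed + 1)
    y = rng.permutation(cohort.bag_true)
    res = gwas_linear(panel, y, cohort.covariates())
    p = res["p"].dropna().to_numpy()
    return {"rate": float((p < alpha).mean()), "n": len(p)}


def abf_coverage(seed: int, n_loci: int = 500, n_individuals: int = 1500,
                 block_size: int = 25) -> dict:
    """Coverage of the 95% single-causal ABF credible set over simulated
    loci with one planted causal variant each."""
    hits = 0
    for i in range(n_loci):
        cfg = SimConfig(n_individuals=n_individuals, n_variants=block_size,
                        ld_block_size=block_size, block_rho=0.6,
                        n_causal=1, h2_bag=0.0, seed=seed * 1009 + i)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng([cfg.seed, 99])
        causal = int(rng.integers(0, block_size))
        x = panel.dosages[:, causal]
        beta = 0.27
        y = beta * (x - x.mean()) + rng.standard_normal(n_individuals)
        ss = gwas_linear(panel, y)
        index_id = ss.loc[ss["p"].idxmin(), "id"]
        ld = np.array([panel.ld_r(panel.index_of(index_id), j) for j in range(panel.n_variants)])
        cs = abf_credible_set(ss, index_id, ld_to_index=ld, prior_sd=0.3)
        if cs.members["id"].eq(panel.variants["id"].iloc[causal]).any():
            hits += 1
    return {"coverage": hits / n_loci, "n": n_loci}


def go_null_fwer(seed: int, n_datasets: int = 400, n_permutations: int = 400) -> dict:
    """Family-wise error of the joint-aspect GO FWER on fully null gene
    p-values: fraction of replicate datasets with any term at FWER < 0.05."""
    cfg = SimConfig(seed=seed)
    panel = simulate_genotypes(cfg)
    cohort, arch = simulate_cohort(panel, cfg)
    fx = simulate_omics_fixtures(panel, arch, cfg)
    gene_names = fx.genes["symbol"].tolist()
    rng = np.random.default_rng(seed + 7)
    false_positives = 0
    for d in range(n_datasets):
        gr = pd.DataFrame({"gene": gene_names, "p": rng.uniform(size=len(gene_names))})
        res = go_enrichment(gr, fx.go, n_permutations=n_permutations, seed=seed * 131 + d)
        if (res["fwer_joint"] < 0.05).any():
            false_positives += 1
    return {"rate": false_positives / n_datasets, "n": n_datasets}


def power_formula_mc(seed: int, beta: float = 0.0925, maf: float = 0.3,
                     n_rep: int = 2000, n_sim: int = 10000, alpha: float = 0.05) -> dict:
    """Analytic one-tailed replication power versus Monte-Carlo rejection
    frequency at a fixed true standardized beta."""
    se_rep = 1.0 / np.sqrt(n_rep * 2 * maf * (1 - maf))
    analytic = float(stats.norm.sf(stats.norm.isf(alpha) - abs(beta) / se_rep))
    rng = np.random.default_rng(seed + 13)
    b_hat = beta + se_rep * rng.standard_normal(n_sim)
    empirical = float((b_hat / se_rep > stats.norm.isf(alpha)).mean())
    return {"analytic": analytic, "empirical": empirical,
            "gap": abs(analytic - empirical), "n": n_sim}


def gsmr_recovery(seed: int, n_seeds: int = 400, b_xy_true: float = 0.5,
                  n_instruments: int = 30) -> dict:
    """GSMR recovery of a planted causal effect over replicate two-sample
    summary simulations: mean estimate and 2-SE (~95%) CI coverage."""
    base = SimConfig(n_individuals=2000, n_variants=150, ld_block_size=5,
                     block_rho=0.3, n_causal=1, seed=seed)
    panel = simulate_genotypes(base)
    estimates, covered = [], 0
    for i in range(n_seeds):
        cfg = SimConfig(n_individuals=2000, n_variants=150, ld_block_size=5,
                        block_rho=0.3, n_causal=1, seed=seed * 2003 + i)
        xg = simulate_exposure_gwas(panel, cfg, n_instruments=n_instruments,
                                    b_xy_true=b_xy_true)
        est = gsmr(xg.exposure, xg.outcome, panel)
        estimates.append(est.b_xy)
        if abs(est.b_xy - b_xy_true) <= 2.0 * est.se:
            covered += 1
    return {"mean_estimate": float(np.mean(estimates)),
            "ci_coverage": covered / n_seeds,
            "mean_se": float(np.mean([abs(e - b_xy_true) for e in estimates])),
            "n": n_seeds}


def winners_curse_bias(seed: int, n_loci: int = 1000, c: float | None = None) -> dict:
    """Winner's-curse correction on ascertained z-statistics.

    Loci carry marginal-power true effects (noncentrality ~ U(4, 5), i.e.
    discovery power roughly 10-35% at genome-wide alpha — the regime the
    correction targets); discovery z-statistics are simulated
    unconditionally and only those clearing the threshold are kept, exactly
    as ascertainment operates.  The measured quantity is the estimator bias
    |E(z_hat - mu)| over ascertained loci: the conditional-likelihood
    correction must reduce it strictly relative to the raw estimates, shrink
    every |z| strictly, and never flip a sign."""
    if c is None:
        c = float(stats.norm.isf(5e-8 / 2))
    rng = np.random.default_rng(seed + 17)
    mus, zs = [], []
    while len(zs) < n_loci:
        mu = rng.uniform(4.0, 5.0, 2000)
        z = mu + rng.standard_normal(2000)
        k = np.abs(z) > c
        mus.extend(mu[k])
        zs.extend(z[k])
    mu = np.array(mus[:n_loci])
    z = np.array(zs[:n_loci])
    z_corr = np.array([winners_curse_z(zi, c) for zi in z])
    raw_bias = float(abs(np.mean(z - mu)))
    corr_bias = float(abs(np.mean(z_corr - mu)))
    return {"raw_bias": raw_bias, "corrected_bias": corr_bias,
            "ratio": corr_bias / raw_bias,
            "sign_flips": int((np.sign(z_corr) != np.sign(z)).sum()),
            "shrunk_all": bool(np.all(np.abs(z_corr) < np.abs(z))),
            "n": n_loci}


def h2_recovery(seed: int, h2: float = 0.25, n_individuals: int = 4000) -> dict:
    """Realized genetic-variance fraction of the generator at a target h2."""
    cfg = SimConfig(n_individuals=n_individuals, n_variants=400, n_causal=30,
                    h2_bag=h2, seed=seed)
    panel = simulate_genotypes(cfg)
    _, arch = simulate_cohort(panel, cfg)
    return {"h2_realized": arch.h2_realized, "n": n_individuals}


def icc_recovery(seed: int, target: float = 0.90, n_individuals: int = 4000,
                 retest_fraction: float = 0.1) -> dict:
    """Estimated ICC(C,1) between test and retest BAG at the generator's
    reliability target."""
    cfg = SimConfig(n_individuals=n_individuals, n_variants=100, n_causal=10,
                    retest_fraction=retest_fraction, retest_icc_target=target,
                    seed=seed)
    panel = simulate_genotypes(cfg)
    cohort, _ = simulate_cohort(panel, cfg)
    idx = cohort.retest_idx
    return {"icc": icc_c1(cohort.bag_true[idx], cohort.bag_retest[idx]),
            "n": len(idx)}


def priority_recovery(seed: int, n_loci: int = 100) -> dict:
    """Fraction of constructed loci where the designated causal gene wins
    the composite priority score, running the full chain: GWAS, credible
    set, SMR, nomination streams, priority score."""
    wins = 0
    for i in range(n_loci):
        cfg = SimConfig(n_individuals=1500, n_variants=40, ld_block_size=20,
                        block_rho=0.6, n_causal=1, h2_bag=0.05,
                        seed=seed * 4001 + i)
        panel = simulate_genotypes(cfg)
        cohort, arch = simulate_cohort(panel, cfg)
        if abs(arch.betas[0]) < 1e-8:
            continue
        fx = simulate_omics_fixtures(panel, arch, cfg, n_mediated=1)
        true_gene = next(iter(fx.manifest["mediated"]))
        ss = gwas_linear(panel, cohort.bag_true, cohort.covariates())
        causal_block = panel.block_index[arch.causal_idx[0]]
        locus_ss = ss[pd.Series(panel.block_index).eq(causal_block).to_numpy()].reset_index(drop=True)
        index_id = locus_ss.loc[locus_ss["p"].idxmin(), "id"]
        gi = panel.index_of(index_id)
        ld = np.array([panel.ld_r(gi, panel.index_of(v)) for v in locus_ss["id"]])
        cs = abf_credible_set(locus_ss, index_id, ld_to_index=ld)
        strong = set(locus_ss.loc[np.abs(ld) ** 2 > 0.8, "id"])
        out_by_id = ss.rename(columns={"id": "id"}).copy()
        smr_res = []
        for gene, grp in fx.eqtl.groupby("gene"):
            eq_ld = np.array([panel.ld_r(panel.index_of(grp["variant"].iloc[grp["p"].to_numpy().argmin()]),
                                         panel.index_of(v)) for v in grp["variant"]])
            smr_res.append(smr_heidi(grp.reset_index(drop=True), out_by_id, ld=eq_ld))
        smr_df = smr_table(smr_res)
        index_variant = {"id": index_id,
                         "chrom": locus_ss.loc[locus_ss["id"] == index_id, "chrom"].iloc[0],
                         "pos": int(locus_ss.loc[locus_ss["id"] == index_id, "pos"].iloc[0])}
        nom = nominate_genes(
            f"locus{i}", index_variant, cs, fx.genes, cadd=fx.cadd,
            eqtl_single=fx.eqtl_single, eqtl_multi=fx.eqtl_multi,
            smr_eqtl=smr_df[smr_df["probe_type"] == "eQTL"] if len(smr_df) else None,
            smr_sqtl=None, pops=fx.pops, strong_ld_ids=strong,
        )
        if len(nom.table) == 0:
            continue
        res = priority_score(nom)
        if res.winner == true_gene:
            wins += 1
    return {"rate": wins / n_loci, "n": n_loci}


class _OracleLearner:
    """Deterministic learner predicting the training-set mean (used to
    exercise protocol structure cheaply)."""

    def __init__(self):
        self.mu = 0.0

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self

    def fit(self, X, y):
        self.mu = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.mu)


def prediction_tensor_cardinality(seed: int, n_repeats: int = 100) -> dict:
    """Prediction-tensor cardinality for 2 tissues x 3 learners x R repeats
    (600 estimates per individual at R = 100)."""
    from sklearn.dummy import DummyRegressor
    from sklearn.linear_model import LinearRegression, Ridge

    rng = np.random.default_rng(seed + 23)
    n, q = 60, 8
    feats = {"gm": rng.standard_normal((n, q)), "wm": rng.standard_normal((n, q))}
    age = rng.uniform(45, 82, n)
    plan = CrossPredictionPlan(
        n_folds=10, n_repeats=n_repeats, n_components=5,
        learners=[("ridge", Ridge()), ("lin", LinearRegression()),
                  ("mean", DummyRegressor())],
        seed=seed,
    )
    oof = crosspredict_ensemble(feats, age, plan)
    return {"estimates_per_individual": oof.estimates_per_individual, "n": n}


def stacking_gain(seed: int, n: int = 2000, noise_sd: float = 3.0) -> dict:
    """Stacked MSE versus the best single learner on a constructed tensor
    of two learners with independent errors."""
    rng = np.random.default_rng(seed + 29)
    age = rng.uniform(45, 82, n)
    tensor = np.empty((n, 1, 2, 1))
    tensor[:, 0, 0, 0] = age + noise_sd * rng.standard_normal(n)
    tensor[:, 0, 1, 0] = age + noise_sd * rng.standard_normal(n)
    plan = CrossPredictionPlan(n_repeats=1, seed=seed)
    oof = OofPredictions(tensor=tensor, tissues=["gm"], learner_names=["a", "b"], plan=plan)
    est = stack_predictions(oof, age, plan)
    stacked_mse = float(np.mean((est.per_tissue["gm"] - age) ** 2))
    single = [float(np.mean((tensor[:, 0, l, 0] - age) ** 2)) for l in range(2)]
    return {"stacked_mse": stacked_mse, "best_single_mse": min(single),
            "ratio": stacked_mse / min(single), "n": n}
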