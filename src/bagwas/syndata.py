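"""Synthetic cohort, genotype and omics-fixture generation.

Every downstream stage of the toolkit (age prediction, GWAS, meta-analysis,
conditional selection, fine-mapping, SMR, gene prioritization, MR, PGS) is
exercised on data produced here, so the generator plants known ground truth:

* LD-block genotypes: a latent Gaussian AR(1) process per block, thresholded
  per haplotype, gives Hardy-Weinberg dosages with tunable r2 decay and zero
  between-block correlation in expectation.
* A quantitative brain-age-gap (BAG) phenotype with additive causal variants
  at a configurable SNP-heritability, small site/sex/TIV covariate effects
  and Gaussian noise.
* Age-dependent imaging features whose noiseless linear readout reproduces
  (age + BAG) exactly, plus test-retest replicates at a target ICC.
* Mediation-consistent eQTL/sQTL fixtures for SMR, CADD/PoPS-like score
  tables and a small GO DAG.
* A two-sample exposure GWAS with a planted causal effect on BAG for MR.

All randomness derives from ``SimConfig.seed`` through per-operation seed
streams, so an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


# seed-stream offsets: one stream per generator operation
_STREAM_GENO = 0
_STREAM_COHORT = 1
_STREAM_OMICS = 2
_STREAM_EXPOSURE = 3

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

_CHROM_BY_PLOIDY = {"diploid": "1", "chrX": "X", "chrY": "Y", "chrXY": "XY"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a desk-scale version of a mid-60s neuroimaging-genetics
    cohort: ages 45.2-81.9 years, MAF > 0.01 common variants in LD blocks,
    BAG standard deviation ~3 years with h2 = 0.25, and a test-retest subset
    with target ICC 0.90.
    """

    n_individuals: int = 2000
    n_variants: int = 600
    ld_block_size: int = 20
    block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 30
    h2_bag: float = 0.25
    age_range: tuple[float, float] = (45.2, 81.9)
    n_features_per_tissue: int = 30
    feature_noise_sd: float = 2.0
    retest_fraction: float = 0.1
    retest_icc_target: float = 0.90
    n_sites: int = 4
    seed: int = 0
    # free parameters of the phenotype model (documented in docs/methods.md)
    bag_sd: float = 3.0
    site_effect_sd: float = 0.3
    sex_effect: float = 0.2
    tiv_effect: float = 0.002
    n_nuisance_latents: int = 5
    variant_spacing: int = 5000
    block_gap: int = 20_000_000

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0 <= self.block_rho < 1):
            raise ConfigError("block_rho must be in [0, 1)")
        if not (0 <= self.h2_bag < 1):
            raise ConfigError("h2_bag must be in [0, 1)")
        if self.n_causal > self.n_variants:
            raise ConfigError("n_causal cannot exceed n_variants")
        for name in ("retest_fraction", "retest_icc_target"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be a fraction in [0, 1]")
        if self.n_features_per_tissue < self.n_nuisance_latents + 1:
            raise ConfigError("need more features than nuisance latents for an exact readout")


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant table.

    ``variants`` columns: chrom, pos (1-based), id, a1 (effect allele), a2,
    maf, ploidy_class, info. Dosages are 0-2 for diploid/chrX/chrXY panels
    and 0-1 for chrY.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    block_index: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def dosage_scale(self) -> int:
        return 1 if (self.variants["ploidy_class"] == "chrY").all() else 2

    def index_of(self, variant_id: str) -> int:
        pos = self.variants.index[self.variants["id"] == variant_id]
        if len(pos) != 1:
            raise KeyError(f"variant {variant_id!r} not uniquely present in panel")
        return int(pos[0])

    def ld_r(self, i: int, j: int) -> float:
        """Pearson correlation between two dosage columns."""
        x, y = self.dosages[:, i], self.dosages[:, j]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    def ld_matrix(self, idx: np.ndarray) -> np.ndarray:
        sub = self.dosages[:, idx]
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=0)) / sd
        return (z.T @ z) / z.shape[0]


@dataclass
class TraitArchitecture:
    """Ground truth of the planted genetic architecture."""

    causal_ids: list[str]
    causal_idx: np.ndarray
    betas: np.ndarray  # years per effect-allele copy
    h2_realized: float


@dataclass
class SyntheticCohort:
    """Per-individual covariates, imaging features and the true BAG."""

    table: pd.DataFrame  # id, sex, age, site, tiv, array, pc1..pc5
    features_gm: np.ndarray
    features_wm: np.ndarray
    bag_true: np.ndarray
    bag_retest: np.ndarray
    retest_idx: np.ndarray
    features_gm_retest: np.ndarray
    features_wm_retest: np.ndarray

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy()

    def covariates(self, pcs: int = 5) -> pd.DataFrame:
        """Covariate frame for association models: sex, age, age^2, TIV,
        site, genotyping array and genetic principal components."""
        t = self.table
        cov = pd.DataFrame(
            {
                "sex": t["sex"],
                "age": t["age"],
                "age2": t["age"] ** 2,
                "tiv": t["tiv"],
                "array": t["array"],
            }
        )
        site = pd.get_dummies(t["site"], prefix="site", drop_first=True).astype(float)
        cov = pd.concat([cov, site], axis=1)
        for k in range(1, pcs + 1):
            cov[f"pc{k}"] = t[f"pc{k}"]
        return cov


@dataclass
class OmicsFixture:
    """Gene models, QTL summary tables, score tables and a GO DAG.

    ``manifest`` records the generator's intent (mediated genes, planted
    ratios, filter-boundary expectations) for parameter-recovery tests.
    """

    genes: pd.DataFrame
    eqtl: pd.DataFrame
    sqtl: pd.DataFrame
    eqtl_single: pd.DataFrame
    eqtl_multi: pd.DataFrame
    cadd: pd.DataFrame
    pops: pd.DataFrame
    go: pd.DataFrame
    manifest: dict = field(default_factory=dict)


@dataclass
class ExposureGWAS:
    """Two-sample summary statistics for MR with a planted causal effect."""

    exposure: pd.DataFrame  # COJO .ma columns: SNP A1 A2 freq b se p N
    outcome: pd.DataFrame
    b_xy_true: float
    pleiotropy_sd: float
    instrument_ids: list[str]
    gamma_true: np.ndarray
    exposure_errors: np.ndarray
    outcome_errors: np.ndarray


def simulate_genotypes(config: SimConfig, ploidy_class: str = "diploid") -> GenotypePanel:
    """Block-diagonal LD genotypes via a thresholded latent AR(1) process.

    Per block, each haplotype carries a latent Gaussian AR(1) series with
    parameter ``block_rho``; the allele is present where the latent value
    falls below the per-variant quantile of its allele frequency.  Summing
    haplotypes yields Hardy-Weinberg dosages.  Blocks are independent and
    separated by ``block_gap`` bp so LD windows never span blocks.
    """
    if ploidy_class not in _CHROM_BY_PLOIDY:
        raise ConfigError(f"unknown ploidy class {ploidy_class!r}")
    rng = np.random.default_rng([config.seed, _STREAM_GENO])
    n, m = config.n_individuals, config.n_variants
    bs = config.ld_block_size
    n_blocks = math.ceil(m / bs)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    thresh = norm.ppf(maf)
    n_hap = 1 if ploidy_class == "chrY" else 2
    rho = config.block_rho
    dos = np.zeros((n, m))
    block_index = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=np.int64)
    cur = 1
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, m)
        k = hi - lo
        block_index[lo:hi] = b
        pos[lo:hi] = cur + np.arange(k, dtype=np.int64) * config.variant_spacing
        cur = int(pos[hi - 1]) + config.block_gap
        for _ in range(n_hap):
            z = np.empty((n, k))
            z[:, 0] = rng.standard_normal(n)
            if k > 1:
                eps = rng.standard_normal((n, k - 1))
                c = math.sqrt(1.0 - rho**2)
                for j in range(1, k):
                    z[:, j] = rho * z[:, j - 1] + c * eps[:, j - 1]
            dos[:, lo:hi] += (z < thresh[lo:hi]).astype(float)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    a1 = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    a2 = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    variants = pd.DataFrame(
        {
            "chrom": _CHROM_BY_PLOIDY[ploidy_class],
            "pos": pos,
            "id": [f"rs{i + 1}" for i in range(m)],
            "a1": a1,
            "a2": a2,
            "maf": maf,
            "ploidy_class": ploidy_class,
            "info": 1.0,
        }
    )
    return GenotypePanel(variants=variants, dosages=dos, block_index=block_index)


def simulate_cohort(panel: GenotypePanel, config: SimConfig) -> tuple[SyntheticCohort, TraitArchitecture]:
    """Plant the BAG phenotype and age-dependent imaging features.

    bag_true = centered G@beta (scaled to ``h2_bag`` of a ``bag_sd``^2
    phenotypic variance) + site/sex/TIV effects + Gaussian noise.  Features
    are a linear readout of (age + bag_true) plus nuisance latents and
    measurement noise; the retest session replaces bag_true with
    lambda*bag_true + sqrt(1-lambda^2)*fresh noise, lambda being the ICC
    target (the consistency ICC of two equal-variance sessions equals their
    correlation).
    """
    if panel.n_individuals != config.n_individuals:
        raise ConfigError("panel and config disagree on the number of individuals")
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    n = config.n_individuals
    sex = rng.integers(0, 2, n).astype(float)
    age = rng.uniform(config.age_range[0], config.age_range[1], n)
    site = rng.integers(0, config.n_sites, n)
    tiv = 1400.0 + 120.0 * rng.standard_normal(n) + 100.0 * sex
    array = rng.integers(0, 2, n).astype(float)
    pcs = rng.standard_normal((n, 5))

    causal_idx = np.sort(rng.choice(panel.n_variants, config.n_causal, replace=False))
    b_raw = rng.standard_normal(config.n_causal)
    Gc = panel.dosages[:, causal_idx]
    g = (Gc - Gc.mean(axis=0)) @ b_raw
    target_var_g = config.h2_bag * config.bag_sd**2
    if config.h2_bag > 0 and g.var() > 0:
        scale = math.sqrt(target_var_g / g.var())
    else:
        scale = 0.0
    betas = b_raw * scale
    g = g * scale

    site_eff = rng.normal(0.0, config.site_effect_sd, config.n_sites)
    cov_part = (
        site_eff[site]
        + config.sex_effect * (sex - 0.5)
        + config.tiv_effect * (tiv - tiv.mean())
    )
    var_noise = config.bag_sd**2 - g.var() - cov_part.var()
    if var_noise <= 0:
        raise ConfigError("h2_bag plus covariate effects exceed the phenotypic variance")
    bag_true = g + cov_part + math.sqrt(var_noise) * rng.standard_normal(n)

    q, k = config.n_features_per_tissue, config.n_nuisance_latents
    lam = config.retest_icc_target
    mu, sd = bag_true.mean(), bag_true.std()
    bag_retest = mu + lam * (bag_true - mu) + math.sqrt(max(0.0, 1 - lam**2)) * sd * rng.standard_normal(n)
    n_retest = int(round(config.retest_fraction * n))
    retest_idx = np.sort(rng.choice(n, n_retest, replace=False)) if n_retest else np.array([], dtype=int)

    def make_tissue(signal, signal_retest):
        w = rng.normal(0.0, 1.0, q)
        B = rng.normal(0.0, 1.0, (q, k))
        U = rng.standard_normal((n, k))
        noise1 = rng.standard_normal((n, q)) * config.feature_noise_sd
        f1 = np.outer(signal, w) + U @ B.T + noise1
        U2 = rng.standard_normal((len(retest_idx), k))
        noise2 = rng.standard_normal((len(retest_idx), q)) * config.feature_noise_sd
        f2 = np.outer(signal_retest[retest_idx], w) + U2 @ B.T + noise2
        return f1, f2

    s1 = age + bag_true
    s2 = age + bag_retest
    features_gm, features_gm_retest = make_tissue(s1, s2)
    features_wm, features_wm_retest = make_tissue(s1, s2)

    table = pd.DataFrame(
        {
            "id": [f"I{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "site": site,
            "tiv": tiv,
            "array": array,
        }
    )
    for j in range(5):
        table[f"pc{j + 1}"] = pcs[:, j]

    cohort = SyntheticCohort(
        table=table,
        features_gm=features_gm,
        features_wm=features_wm,
        bag_true=bag_true,
        bag_retest=bag_retest,
        retest_idx=retest_idx,
        features_gm_retest=features_gm_retest,
        features_wm_retest=features_wm_retest,
    )
    h2_realized = float(g.var() / bag_true.var()) if bag_true.var() > 0 else 0.0
    arch = TraitArchitecture(
        causal_ids=[panel.variants["id"].iloc[i] for i in causal_idx],
        causal_idx=causal_idx,
        betas=betas,
        h2_realized=h2_realized,
    )
    return cohort, arch


def _block_genes(panel: GenotypePanel, arch: TraitArchitecture) -> pd.DataFrame:
    """Two non-overlapping genes per LD block; the gene containing the
    block's causal variant (if any) is its designated 'true' gene."""
    rows = []
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].iloc[0]
    causal_set = set(arch.causal_idx.tolist())
    for b in np.unique(panel.block_index):
        idx = np.where(panel.block_index == b)[0]
        if len(idx) < 4:
            continue
        lo, hi = pos[idx[0]], pos[idx[-1]]
        mid = (lo + hi) // 2
        spans = [(lo - 500, mid - 1000), (mid + 1000, hi + 500)]
        for gi, (s, e) in enumerate(spans):
            length = e - s
            exon_starts = [s, s + int(length * 0.4), s + int(length * 0.8)]
            exon_ends = [s + int(length * 0.2), s + int(length * 0.6), e]
            strand = "+" if gi == 0 else "-"
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(e),
                    "strand": strand,
                    "symbol": f"G{b:03d}{'AB'[gi]}",
                    "exon_starts": ";".join(str(x) for x in exon_starts),
                    "exon_ends": ";".join(str(x) for x in exon_ends),
                    "cds_start": int(s + length * 0.05),
                    "cds_end": int(e - length * 0.05),
                    "block": int(b),
                }
            )
    genes = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    # make sure each causal variant lies inside exactly one gene of its block
    for ci in causal_set:
        p, b = pos[ci], panel.block_index[ci]
        mask = genes["block"] == b
        if not mask.any():
            continue
        inside = mask & (genes["start"] <= p) & (genes["end"] >= p)
        if not inside.any():
            gsub = genes.loc[mask]
            nearest = (gsub[["start", "end"]].apply(lambda r: min(abs(r.start - p), abs(r.end - p)), axis=1)).idxmin()
            s, e = genes.loc[nearest, ["start", "end"]]
            genes.loc[nearest, "start"] = int(min(s, p - 100))
            genes.loc[nearest, "end"] = int(max(e, p + 100))
    return genes


def _projected_qtl(panel, gene, causal_i, beta_zx_c, eqtl_n, rng, add_noise, tissue, min_r2=0.02):
    """Marginal QTL summary rows implied by a single causal cis-variant."""
    x = panel.dosages
    vc = x[:, causal_i]
    varc = vc.var()
    var_expr = beta_zx_c**2 * varc * 1.5  # expression R2 = 2/3 at the causal
    block = panel.block_index[causal_i]
    rows = []
    for j in np.where(panel.block_index == block)[0]:
        xj = x[:, j]
        varj = xj.var()
        if varj == 0:
            continue
        cov = float(np.mean((xj - xj.mean()) * (vc - vc.mean())))
        r2 = cov**2 / (varj * varc)
        if j != causal_i and r2 < min_r2:
            continue
        b_true = beta_zx_c * cov / varj
        se = math.sqrt(max(var_expr - b_true**2 * varj, 1e-8) / (eqtl_n * varj))
        b_obs = b_true + rng.normal(0.0, se) if add_noise else b_true
        z = b_obs / se
        rows.append(
            {
                "gene": gene,
                "variant": panel.variants["id"].iloc[j],
                "tissue": tissue,
                "beta_zx": b_obs,
                "se_zx": se,
                "p": 2 * norm.sf(abs(z)),
                "m_value": np.nan,
                "n_tissues": np.nan,
                "re2_p": np.nan,
                "b_zx_true": b_true,
            }
        )
    return rows


def _go_fixture(rng, genes: pd.DataFrame, enriched: dict[str, list[str]]) -> pd.DataFrame:
    """Small acyclic GO DAG: one root per aspect, two levels below it."""
    symbols = genes["symbol"].tolist()
    rows = []
    for aspect in ("BP", "MF", "CC"):
        root = f"GO:{aspect}:root"
        rows.append({"term": root, "aspect": aspect, "parents": "", "genes": ";".join(symbols)})
        mids = []
        for i in range(4):
            mid = f"GO:{aspect}:mid{i}"
            mids.append(mid)
            members = set()
            for j in range(3):
                leaf = f"GO:{aspect}:leaf{i}_{j}"
                k = int(rng.integers(5, 13))
                leaf_genes = list(rng.choice(symbols, size=min(k, len(symbols)), replace=False))
                if aspect in enriched and i == 0 and j == 0:
                    leaf_genes = sorted(set(leaf_genes) | set(enriched[aspect]))
                rows.append({"term": leaf, "aspect": aspect, "parents": mid, "genes": ";".join(leaf_genes)})
                members.update(leaf_genes)
            extra = list(rng.choice(symbols, size=min(4, len(symbols)), replace=False))
            members.update(extra)
            rows.append({"term": mid, "aspect": aspect, "parents": root, "genes": ";".join(sorted(members))})
    return pd.DataFrame(rows)


def simulate_omics_fixtures(
    panel: GenotypePanel,
    arch: TraitArchitecture,
    config: SimConfig,
    beta_xy_eqtl: float = 0.4,
    beta_xy_sqtl: float = 0.3,
    eqtl_n: int = 2500,
    n_mediated: int | None = None,
    add_noise: bool = True,
) -> OmicsFixture:
    """Gene models, mediation-consistent QTLs, score tables and a GO DAG.

    A designated subset of causal variants is 'mediated': the causal
    variant's eQTL effect is beta_zx = beta_bag / beta_xy, so the implied
    per-instrument ratio beta_zy/beta_zx equals the planted beta_xy exactly
    in the noise-free projection (every LD neighbor inherits the same ratio).
    Multi-tissue fixtures include records on both sides of the lookup
    filters (>=10 tissues; m >= 0.9 in >=50% of tissues; RE2 p < 5e-8).
    """
    rng = np.random.default_rng([config.seed, _STREAM_OMICS])
    genes = _block_genes(panel, arch)
    if n_mediated is None:
        n_mediated = min(8, len(arch.causal_idx))
    pos = panel.variants["pos"].to_numpy()

    mediated = {}
    eqtl_rows, sqtl_rows, truth_rows = [], [], []
    usable = [ci for ci in arch.causal_idx if abs(arch.betas[list(arch.causal_idx).index(ci)]) > 1e-8]
    for ci in usable[:n_mediated]:
        bi = list(arch.causal_idx).index(ci)
        beta_bag = arch.betas[bi]
        b = panel.block_index[ci]
        sub = genes[(genes["block"] == b) & (genes["start"] <= pos[ci]) & (genes["end"] >= pos[ci])]
        if sub.empty:
            raise ConfigError(f"mediated causal variant {panel.variants['id'].iloc[ci]} has no containing gene")
        gene = sub["symbol"].iloc[0]
        beta_zx = beta_bag / beta_xy_eqtl
        rows = _projected_qtl(panel, gene, ci, beta_zx, eqtl_n, rng, add_noise, "cortex")
        eqtl_rows.extend(rows)
        beta_zx_s = beta_bag / beta_xy_sqtl
        sqtl_rows.extend(_projected_qtl(panel, gene + ".s1", ci, beta_zx_s, eqtl_n, rng, add_noise, "cortex"))
        for r in rows:
            j = panel.index_of(r["variant"])
            xj = panel.dosages[:, j]
            cov = float(np.mean((xj - xj.mean()) * (panel.dosages[:, ci] - panel.dosages[:, ci].mean())))
            truth_rows.append(
                {
                    "gene": gene,
                    "variant": r["variant"],
                    "b_zx_true": r["b_zx_true"],
                    "b_zy_true": beta_bag * cov / xj.var(),
                }
            )
        mediated[gene] = {
            "causal_id": panel.variants["id"].iloc[ci],
            "beta_xy": beta_xy_eqtl,
            "beta_zx": beta_zx,
            "sqtl_gene": gene + ".s1",
            "beta_xy_sqtl": beta_xy_sqtl,
        }

    eqtl = pd.DataFrame(eqtl_rows).drop(columns=["b_zx_true"], errors="ignore")
    sqtl = pd.DataFrame(sqtl_rows).drop(columns=["b_zx_true"], errors="ignore")

    # single-tissue lookup: the true gene is significant in many tissues, its
    # within-block decoy in few
    single_rows = []
    for gene, info in mediated.items():
        n_tiss_true = int(rng.integers(6, 10))
        for t in range(n_tiss_true):
            single_rows.append({"gene": gene, "variant": info["causal_id"], "tissue": f"T{t}", "p": 1e-12})
        block = genes.loc[genes["symbol"] == gene, "block"].iloc[0]
        decoys = genes[(genes["block"] == block) & (genes["symbol"] != gene)]["symbol"]
        for d in decoys:
            single_rows.append({"gene": d, "variant": info["causal_id"], "tissue": "T0", "p": 1e-9})
    eqtl_single = pd.DataFrame(single_rows)

    # multi-tissue lookup with filter-boundary constructs
    multi_rows, multi_expected = [], {}

    def add_multi(gene, variant, n_tissues, frac_m_high, re2_p):
        n_high = int(round(frac_m_high * n_tissues))
        for t in range(n_tissues):
            m = 0.95 if t < n_high else 0.89
            multi_rows.append(
                {"gene": gene, "variant": variant, "tissue": f"T{t}", "m_value": m,
                 "n_tissues": n_tissues, "re2_p": re2_p}
            )
        multi_expected[(gene, variant)] = (n_tissues >= 10) and (n_high / n_tissues >= 0.5) and (re2_p < 5e-8)

    for gene, info in mediated.items():
        add_multi(gene, info["causal_id"], 12, 0.9, 1e-12)
    nonmediated = [s for s in genes["symbol"] if s not in mediated][:4]
    boundary_variants = panel.variants["id"].iloc[:: max(1, panel.n_variants // 5)].tolist()
    specs = [(9, 1.0, 1e-12), (10, 1.0, 1e-12), (12, 0.4, 1e-12), (12, 0.5, 1e-12)]
    for gene, (nt, fm, rp), v in zip(nonmediated, specs, boundary_variants):
        add_multi(gene, v, nt, fm, rp)
    eqtl_multi = pd.DataFrame(multi_rows)

    # CADD-like table: mediated causals are nonsynonymous with high scores
    cadd_rows = []
    mediated_causals = {info["causal_id"] for info in mediated.values()}
    for i, vid in enumerate(panel.variants["id"]):
        if vid in mediated_causals:
            cadd_rows.append({"variant": vid, "phred_score": float(rng.uniform(20, 35)), "consequence": "nonsynonymous"})
        elif rng.random() < 0.1:
            cadd_rows.append({"variant": vid, "phred_score": float(rng.uniform(0, 10)), "consequence": "intronic"})
    cadd = pd.DataFrame(cadd_rows)

    pops = pd.DataFrame({"gene": genes["symbol"], "score": rng.standard_normal(len(genes))})
    for gene in mediated:
        pops.loc[pops["gene"] == gene, "score"] += 3.0

    enriched = {"BP": list(mediated)[:4]} if mediated else {}
    go = _go_fixture(rng, genes, enriched)

    manifest = {
        "mediated": mediated,
        "multi_tissue_expected": multi_expected,
        "true_gene_by_causal": {info["causal_id"]: g for g, info in mediated.items()},
        "mediated_truth": pd.DataFrame(truth_rows),
    }
    return OmicsFixture(
        genes=genes, eqtl=eqtl, sqtl=sqtl, eqtl_single=eqtl_single,
        eqtl_multi=eqtl_multi, cadd=cadd, pops=pops, go=go, manifest=manifest,
    )


def simulate_exposure_gwas(
    panel: GenotypePanel,
    config: SimConfig,
    n_instruments: int = 30,
    b_xy_true: float = 0.5,
    n_exposure: int = 20000,
    n_outcome: int = 20000,
    pleiotropy_sd: float = 0.0,
) -> ExposureGWAS:
    """Two-sample exposure/outcome summary statistics for MR.

    One instrument per independent LD block; true exposure effects are sized
    (noncentrality ~8 at the stated sample size) so essentially all planted
    instruments clear p < 5e-8.  Exposure and outcome sampling errors are
    drawn independently, honoring the two-sample contract; the outcome
    effect of each instrument is b_xy_true * gamma (+ optional pleiotropy).
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPOSURE])
    n_blocks = len(np.unique(panel.block_index))
    if n_instruments > n_blocks:
        raise ConfigError(
            f"requested {n_instruments} instruments but the panel has only {n_blocks} independent blocks"
        )
    instr_idx = []
    for b in np.unique(panel.block_index)[:n_instruments]:
        members = np.where(panel.block_index == b)[0]
        instr_idx.append(int(members[len(members) // 2]))
    instr_idx = np.array(instr_idx)
    var = panel.variants.iloc[instr_idx]
    freq = var["maf"].to_numpy()
    se_x = 1.0 / np.sqrt(2 * freq * (1 - freq) * n_exposure)
    gamma = np.sign(rng.standard_normal(n_instruments)) * se_x * (8.0 + np.abs(rng.standard_normal(n_instruments)))
    e1 = se_x * rng.standard_normal(n_instruments)
    b_zx = gamma + e1
    se_y = 1.0 / np.sqrt(2 * freq * (1 - freq) * n_outcome)
    alpha = pleiotropy_sd * rng.standard_normal(n_instruments) if pleiotropy_sd > 0 else np.zeros(n_instruments)
    e2 = se_y * rng.standard_normal(n_instruments)
    b_zy = b_xy_true * gamma + alpha + e2

    def ma(b, se, n):
        z = b / se
        return pd.DataFrame(
            {
                "SNP": var["id"].to_numpy(),
                "A1": var["a1"].to_numpy(),
                "A2": var["a2"].to_numpy(),
                "freq": freq,
                "b": b,
                "se": se,
                "p": 2 * norm.sf(np.abs(z)),
                "N": n,
            }
        )

    return ExposureGWAS(
        exposure=ma(b_zx, se_x, n_exposure),
        outcome=ma(b_zy, se_y, n_outcome),
        b_xy_true=b_xy_true,
        pleiotropy_sd=pleiotropy_sd,
        instrument_ids=var["id"].tolist(),
        gamma_true=gamma,
        exposure_errors=e1,
        outcome_errors=e2,
    )
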