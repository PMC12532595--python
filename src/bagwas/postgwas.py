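"""Credible sets, variant-to-gene mapping, SMR/HEIDI and gene prioritization.

Fine-mapping uses a single-causal approximate Bayes factor model per locus
(Wakefield ABF): per-variant posterior inclusion probabilities are the
normalized ABFs and the 95% credible set is the minimal PIP-descending
prefix reaching 0.95.  SMR tests whether a variant's trait effect is
mediated through gene expression via the ratio beta_xy = beta_zy/beta_zx of
the top cis-instrument, with the HEIDI heterogeneity test separating
mediation/pleiotropy from linkage.  Seven evidence streams nominate genes
per locus and a composite priority score picks the winner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

GENOME_WIDE_P = 5e-8

CATEGORY_ANNOTATION = "annotation"
RANKED_CATEGORIES = ("cadd", "smr_eqtl", "smr_sqtl", "eqtl_single", "eqtl_multi", "pops")

_PRECEDENCE = ["exonic", "splice", "utr", "intronic", "upstream", "downstream", "intergenic"]


def _parse_ints(s) -> list[int]:
    if isinstance(s, str) and s:
        return [int(x) for x in s.split(";")]
    return []


def map_variant_to_gene(chrom, pos: int, genes: pd.DataFrame) -> tuple[str, str]:
    """Positional functional category and gene for one variant.

    Precedence: exonic > splice region (within 2 bp of an exon boundary,
    intronic side) > UTR > intronic > up/downstream (<= 1 kb) > intergenic;
    intergenic variants map to the nearest gene by bp distance, ties to the
    smaller start coordinate.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("empty gene model set")
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no gene models on chromosome {chrom}")
    best = None  # (precedence_index, gene)
    for _, g in sub.iterrows():
        cat = None
        if g["start"] <= pos <= g["end"]:
            exon_starts = _parse_ints(g.get("exon_starts"))
            exon_ends = _parse_ints(g.get("exon_ends"))
            in_exon = any(s <= pos <= e for s, e in zip(exon_starts, exon_ends))
            if in_exon:
                cds_s, cds_e = g.get("cds_start", g["start"]), g.get("cds_end", g["end"])
                cat = "exonic" if cds_s <= pos <= cds_e else "utr"
            else:
                near_boundary = any(
                    0 < pos - e <= 2 or 0 < s - pos <= 2
                    for s, e in zip(exon_starts, exon_ends)
                )
                cat = "splice" if near_boundary else "intronic"
        elif g["start"] - 1000 <= pos < g["start"]:
            cat = "upstream" if g["strand"] == "+" else "downstream"
        elif g["end"] < pos <= g["end"] + 1000:
            cat = "downstream" if g["strand"] == "+" else "upstream"
        if cat is not None:
            rank = _PRECEDENCE.index(cat)
            if best is None or rank < best[0]:
                best = (rank, cat, g["symbol"])
    if best is not None:
        return best[1], best[2]
    # intergenic: nearest gene by distance, tie -> smaller start
    dist = np.minimum(np.abs(sub["start"] - pos), np.abs(sub["end"] - pos))
    order = sub.assign(_d=dist).sort_values(["_d", "start"])
    return "intergenic", order["symbol"].iloc[0]


@dataclass
class CredibleSet:
    locus_id: str
    table: pd.DataFrame  # id, z, pip, in_set (PIP-descending)
    assigned: bool

    @property
    def size(self) -> int:
        return int(self.table["in_set"].sum())

    @property
    def members(self) -> pd.DataFrame:
        return self.table[self.table["in_set"]]


def abf_credible_set(
    locus_sumstats: pd.DataFrame,
    index_id: str,
    ld_to_index: np.ndarray | None = None,
    prior_sd: float = 0.3,
    coverage: float = 0.95,
    assign_r2: float = 0.8,
    assign_window_kb: float = 3000,
    gw_threshold: float = GENOME_WIDE_P,
    locus_id: str | None = None,
) -> CredibleSet:
    """Single-causal Wakefield ABF credible set for one locus.

    ABF = sqrt(1-r) * exp(z^2 r / 2) with r = W/(W + se^2), W = prior_sd^2.
    PIPs are ABFs normalized over the locus (they sum to one under the
    single-causal assumption); the credible set is the minimal PIP-ordered
    prefix with cumulative PIP >= ``coverage``.  The set is assigned to the
    locus if it contains at least one genome-wide significant credible
    variant in strong LD (r^2 > ``assign_r2``) within ``assign_window_kb``
    of the index variant.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    ss = locus_sumstats.reset_index(drop=True)
    z = (ss["beta"] / ss["se"]).to_numpy(dtype=float)
    se2 = ss["se"].to_numpy(dtype=float) ** 2
    W = prior_sd**2
    r = W / (W + se2)
    log_abf = 0.5 * np.log1p(-r) + z**2 * r / 2.0
    pip = np.exp(log_abf - logsumexp(log_abf))
    order = np.argsort(-pip, kind="stable")
    in_set = np.zeros(len(ss), dtype=bool)
    csum = 0.0
    for i in order:
        in_set[i] = True
        csum += pip[i]
        if csum >= coverage:
            break
    tab = ss.copy()
    tab["z"] = z
    tab["pip"] = pip
    tab["in_set"] = in_set
    tab = tab.iloc[order].reset_index(drop=True)
    idx_row = ss.index[ss["id"] == index_id]
    assigned = False
    if len(idx_row):
        ipos = ss.loc[idx_row[0], "pos"]
        if ld_to_index is None:
            ld_to_index = np.where(ss["id"] == index_id, 1.0, 0.0)
        ld = np.asarray(ld_to_index, dtype=float)
        window = assign_window_kb * 1000.0
        for i in range(len(ss)):
            if not in_set[i]:
                continue
            if ss.loc[i, "p"] < gw_threshold and ld[i] ** 2 > assign_r2 and abs(ss.loc[i, "pos"] - ipos) <= window:
                assigned = True
                break
    return CredibleSet(locus_id=locus_id or index_id, table=tab, assigned=assigned)


@dataclass
class SmrResult:
    gene: str
    probe_type: str
    beta_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float
    n_instruments: int
    top_instrument: str
    fdr: float = np.nan
    passes: bool = False


def smr_heidi(
    eqtl_records: pd.DataFrame,
    outcome_sumstats: pd.DataFrame,
    ld: np.ndarray | None = None,
    probe_type: str = "eQTL",
    instrument_p: float = GENOME_WIDE_P,
    heidi_r2_range: tuple[float, float] = (0.05, 0.9),
    max_heidi_instruments: int = 20,
) -> SmrResult | None:
    """SMR ratio test plus the HEIDI linkage-heterogeneity test for one gene.

    ``eqtl_records`` columns: variant, beta_zx, se_zx, p; ``outcome_sumstats``
    indexed or keyed by variant with beta, se.  The top instrument (smallest
    eQTL p) must clear ``instrument_p``; beta_xy = beta_zy/beta_zx with the
    delta-method SE |beta_xy| sqrt(se_zy^2/beta_zy^2 + se_zx^2/beta_zx^2).
    HEIDI compares per-instrument ratios of secondary instruments
    (``heidi_r2_range`` r^2 against the top, at most
    ``max_heidi_instruments``) with the top instrument's ratio via an
    LD-aware quadratic form, chi-square with m-1 df; small p indicates
    linkage rather than mediation/pleiotropy.  Returns None when no valid
    instrument exists.
    """
    eq = eqtl_records.reset_index(drop=True)
    out = outcome_sumstats.set_index("id") if "id" in outcome_sumstats.columns else outcome_sumstats
    common = [v for v in eq["variant"] if v in out.index]
    eq = eq[eq["variant"].isin(common)].reset_index(drop=True)
    if eq.empty:
        return None
    top_i = int(eq["p"].idxmin())
    if eq.loc[top_i, "p"] >= instrument_p:
        return None
    gene = eq["gene"].iloc[0] if "gene" in eq.columns else ""

    def row(i):
        v = eq.loc[i, "variant"]
        return (eq.loc[i, "beta_zx"], eq.loc[i, "se_zx"],
                float(out.loc[v, "beta"]), float(out.loc[v, "se"]))

    bzx, se_zx, bzy, se_zy = row(top_i)
    beta_xy = bzy / bzx
    se_xy = abs(beta_xy) * math.sqrt(se_zy**2 / bzy**2 + se_zx**2 / bzx**2) if bzy != 0 else abs(se_zy / bzx)
    z = beta_xy / se_xy
    p_smr = 2 * stats.norm.sf(abs(z))

    p_heidi = np.nan
    sec = []
    if ld is not None:
        lo, hi = heidi_r2_range
        for i in range(len(eq)):
            if i == top_i:
                continue
            r2 = float(ld[i]) ** 2
            if lo < r2 < hi:
                sec.append(i)
        sec = sorted(sec, key=lambda i: eq.loc[i, "p"])[:max_heidi_instruments]
    if sec:
        idx = [top_i] + sec
        m = len(idx)
        b = np.empty(m)
        var_b = np.empty(m)
        bzx_v = np.empty(m)
        sezy_v = np.empty(m)
        sezx_v = np.empty(m)
        for k, i in enumerate(idx):
            bx, sx, by, sy = row(i)
            b[k] = by / bx
            var_b[k] = (sy**2 + b[k] ** 2 * sx**2) / bx**2
            bzx_v[k], sezy_v[k], sezx_v[k] = bx, sy, sx
        r_vec = np.array([1.0] + [float(ld[i]) for i in sec])
        # LD-aware covariance of ratio estimates (first-order delta method)
        C = np.empty((m, m))
        for a in range(m):
            for c in range(m):
                # correlation between instruments a and c approximated from
                # their LD with the top instrument (exact for a or c = top)
                if a == c:
                    C[a, c] = var_b[a]
                else:
                    if a == 0:
                        rac = r_vec[c]
                    elif c == 0:
                        rac = r_vec[a]
                    else:
                        rac = r_vec[a] * r_vec[c]
                    C[a, c] = rac * (sezy_v[a] * sezy_v[c] + b[a] * b[c] * sezx_v[a] * sezx_v[c]) / (bzx_v[a] * bzx_v[c])
        d = b[1:] - b[0]
        J = np.zeros((m - 1, m))
        J[:, 0] = -1.0
        J[np.arange(m - 1), np.arange(1, m)] = 1.0
        V = J @ C @ J.T
        try:
            T = float(d @ np.linalg.solve(V, d))
        except np.linalg.LinAlgError:
            T = float(d @ np.linalg.pinv(V) @ d)
        p_heidi = float(stats.chi2.sf(T, m - 1))
    return SmrResult(
        gene=gene, probe_type=probe_type, beta_xy=float(beta_xy), se_xy=float(se_xy),
        p_smr=float(p_smr), p_heidi=float(p_heidi),
        n_instruments=1 + len(sec), top_instrument=eq.loc[top_i, "variant"],
    )


def smr_table(results: list[SmrResult], fdr_level: float = 0.05, heidi_p: float = 0.01) -> pd.DataFrame:
    """FDR within probe type across tested genes; passing requires
    FDR < ``fdr_level`` and HEIDI p > ``heidi_p`` (or no HEIDI test)."""
    from .stats import adjust_pvalues

    rows = [vars(r).copy() for r in results if r is not None]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for ptype, grp in df.groupby("probe_type"):
        df.loc[grp.index, "fdr"] = adjust_pvalues(grp["p_smr"].to_numpy(), "bh")
    heidi_ok = df["p_heidi"].isna() | (df["p_heidi"] > heidi_p)
    df["passes"] = (df["fdr"] < fdr_level) & heidi_ok
    return df


def filter_multi_tissue(records: pd.DataFrame, min_tissues: int = 10,
                        m_threshold: float = 0.9, m_fraction: float = 0.5,
                        re2_p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Multi-tissue QTL lookup filter: keep (gene, variant) groups available
    in >= ``min_tissues`` tissues, with m >= ``m_threshold`` in at least
    ``m_fraction`` of tissues, and RE2 meta p < ``re2_p_threshold``."""
    rows = []
    for (gene, variant), grp in records.groupby(["gene", "variant"]):
        n_tiss = int(grp["n_tissues"].iloc[0]) if grp["n_tissues"].notna().any() else len(grp)
        frac = float((grp["m_value"] >= m_threshold).mean())
        re2 = float(grp["re2_p"].min())
        if n_tiss >= min_tissues and frac >= m_fraction and re2 < re2_p_threshold:
            rows.append({"gene": gene, "variant": variant, "n_tissues": n_tiss,
                         "m_fraction": frac, "re2_p": re2})
    return pd.DataFrame(rows)


def _competition_ranks(scores: pd.Series, ascending: bool) -> pd.Series:
    """Ties share the best rank; following ranks are skipped."""
    return scores.rank(method="min", ascending=ascending).astype(int)


@dataclass
class NominationTable:
    locus_id: str
    index_id: str
    index_pos: int
    index_chrom: str
    table: pd.DataFrame  # gene, category, raw, rank
    gene_positions: dict[str, int] = field(default_factory=dict)


def nominate_genes(
    locus_id: str,
    index_variant: dict,
    credible: CredibleSet,
    genes: pd.DataFrame,
    cadd: pd.DataFrame | None = None,
    eqtl_single: pd.DataFrame | None = None,
    eqtl_multi: pd.DataFrame | None = None,
    smr_eqtl: pd.DataFrame | None = None,
    smr_sqtl: pd.DataFrame | None = None,
    pops: pd.DataFrame | None = None,
    strong_ld_ids: set[str] | None = None,
    pops_window_kb: float = 500,
    pops_top: int = 3,
    single_tissue_p: float = GENOME_WIDE_P,
) -> NominationTable:
    """Fill the seven evidence streams for one locus.

    1. annotation: credible-variant PIP mass aggregated per mapped gene
       (intergenic mass accrues to the nearest gene);
    2. cadd: max CADD Phred among nonsynonymous credible variants per gene;
    3./4. SMR eQTL/sQTL passing genes ranked by p;
    5. single-tissue eQTL lookup over the index variant and strong-LD
       neighbors, ranked by the number of significant tissues;
    6. multi-tissue eQTL after the availability/m-value/RE2 filters, ranked
       by tissue count;
    7. PoPS: up to ``pops_top`` genes within ``pops_window_kb`` of the index
       with the highest scores.
    Ranks are competition ranks within category.
    """
    rows = []
    ichrom, ipos = index_variant["chrom"], int(index_variant["pos"])
    strong = set(strong_ld_ids or {index_variant["id"]})

    pip_mass: dict[str, float] = {}
    var_gene: dict[str, str] = {}
    for _, v in credible.members.iterrows():
        cat, gene = map_variant_to_gene(v.get("chrom", ichrom), int(v["pos"]), genes)
        var_gene[v["id"]] = gene
        pip_mass[gene] = pip_mass.get(gene, 0.0) + float(v["pip"])
    if pip_mass:
        s = pd.Series(pip_mass)
        ranks = _competition_ranks(s, ascending=False)
        for gene, val in s.items():
            rows.append({"gene": gene, "category": CATEGORY_ANNOTATION, "raw": val, "rank": int(ranks[gene])})

    if cadd is not None and len(cadd):
        ns = cadd[(cadd["consequence"] == "nonsynonymous") & cadd["variant"].isin(var_gene)]
        if len(ns):
            best = (ns.assign(gene=[var_gene[v] for v in ns["variant"]])
                      .groupby("gene")["phred_score"].max())
            ranks = _competition_ranks(best, ascending=False)
            for gene, val in best.items():
                rows.append({"gene": gene, "category": "cadd", "raw": float(val), "rank": int(ranks[gene])})

    for name, smr_df in (("smr_eqtl", smr_eqtl), ("smr_sqtl", smr_sqtl)):
        if smr_df is None or len(smr_df) == 0:
            continue
        passing = smr_df[smr_df["passes"]]
        if len(passing) == 0:
            continue
        best = passing.groupby("gene")["p_smr"].min()
        ranks = _competition_ranks(best, ascending=True)
        for gene, val in best.items():
            rows.append({"gene": gene, "category": name, "raw": float(val), "rank": int(ranks[gene])})

    if eqtl_single is not None and len(eqtl_single):
        hits = eqtl_single[eqtl_single["variant"].isin(strong) & (eqtl_single["p"] < single_tissue_p)]
        if len(hits):
            counts = hits.groupby("gene")["tissue"].nunique()
            ranks = _competition_ranks(counts.astype(float), ascending=False)
            for gene, val in counts.items():
                rows.append({"gene": gene, "category": "eqtl_single", "raw": float(val), "rank": int(ranks[gene])})

    if eqtl_multi is not None and len(eqtl_multi):
        mt = filter_multi_tissue(eqtl_multi[eqtl_multi["variant"].isin(strong)])
        if len(mt):
            counts = mt.groupby("gene")["n_tissues"].max()
            ranks = _competition_ranks(counts.astype(float), ascending=False)
            for gene, val in counts.items():
                rows.append({"gene": gene, "category": "eqtl_multi", "raw": float(val), "rank": int(ranks[gene])})

    if pops is not None and len(pops):
        gsub = genes[genes["chrom"] == ichrom].copy()
        mid = (gsub["start"] + gsub["end"]) / 2
        near = gsub.loc[(mid - ipos).abs() <= pops_window_kb * 1000, "symbol"]
        cand = pops[pops["gene"].isin(near)].nlargest(pops_top, "score")
        if len(cand):
            s = cand.set_index("gene")["score"]
            ranks = _competition_ranks(s, ascending=False)
            for gene, val in s.items():
                rows.append({"gene": gene, "category": "pops", "raw": float(val), "rank": int(ranks[gene])})

    table = pd.DataFrame(rows, columns=["gene", "category", "raw", "rank"])
    gpos = {g["symbol"]: int((g["start"] + g["end"]) // 2) for _, g in genes.iterrows()}
    return NominationTable(locus_id=locus_id, index_id=index_variant["id"],
                           index_pos=ipos, index_chrom=ichrom, table=table,
                           gene_positions=gpos)


@dataclass
class PriorityResult:
    locus_id: str
    scores: pd.DataFrame  # gene, c_i, p_i
    winner: str
    tie_break_used: bool


def priority_score(nominations: NominationTable) -> PriorityResult:
    """Composite gene priority score.

    P_i = C_i + sum over the six ranked categories of
    2 (n_j + 1 - R_ij) / (n_j (n_j + 1)), where C_i is the credible-variant
    posterior mass of gene i, n_j the number of genes ranked in category j
    and R_ij the gene's competition rank.  Each ranked category contributes
    one point in total across its ranks; the winner is the gene with the
    highest P_i, ties broken by proximity to the index variant.
    """
    t = nominations.table
    for cat, grp in t.groupby("category"):
        if grp["gene"].duplicated().any():
            raise ValueError(f"duplicate gene rows within category {cat!r}")
    genes = sorted(t["gene"].unique())
    c_i = {g: 0.0 for g in genes}
    ann = t[t["category"] == CATEGORY_ANNOTATION]
    for _, r in ann.iterrows():
        c_i[r["gene"]] = float(r["raw"])
    p_i = dict(c_i)
    for cat in RANKED_CATEGORIES:
        grp = t[t["category"] == cat]
        n_j = len(grp)
        if n_j == 0:
            continue
        for _, r in grp.iterrows():
            p_i[r["gene"]] += 2.0 * (n_j + 1 - r["rank"]) / (n_j * (n_j + 1))
    scores = pd.DataFrame({"gene": genes,
                           "c_i": [c_i[g] for g in genes],
                           "p_i": [p_i[g] for g in genes]}).sort_values("p_i", ascending=False)
    top = scores["p_i"].max()
    tied = scores.loc[(top - scores["p_i"]) < 1e-12, "gene"].tolist()
    tie_break = len(tied) > 1
    if tie_break:
        tied.sort(key=lambda g: abs(nominations.gene_positions.get(g, 10**12) - nominations.index_pos))
    return PriorityResult(locus_id=nominations.locus_id, scores=scores.reset_index(drop=True),
                          winner=tied[0], tie_break_used=tie_break)
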