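"""Per-variant association, fixed-effects meta-analysis, stepwise
conditional signal selection and cross-trait locus clumping.

The GWAS is an additive dosage regression with covariates; meta-analysis is
inverse-variance-weighted fixed effects with the usual sample-size and
heterogeneity filters; independent signals are selected by stepwise
conditional analysis (exact joint regression on individual-level data); and
index variants across traits are greedily LD-clumped into loci, with novelty
flagged against a known-variant list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .syndata import GenotypePanel

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-6

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of columns of M after projection onto orthonormal Q."""
    return M - Q @ (Q.T @ M)


def _covariate_design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    C = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return C


def gwas_linear(panel: GenotypePanel, phenotype: np.ndarray, covariates=None) -> pd.DataFrame:
    """Additive-dosage OLS per variant: phenotype ~ dosage + covariates.

    Implemented by Frisch-Waugh residualization, which is exact: phenotype
    and each dosage column are residualized on the covariates (plus
    intercept) and the per-variant slope/SE/t follow from the simple
    regression of residuals with df = n - k_cov - 2.  Dosages enter on their
    native ploidy scale.  Monomorphic variants yield an NA row flagged with
    a reason code rather than being silently dropped.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if panel.n_individuals != n:
        raise ValueError("phenotype not aligned with panel")
    C = _covariate_design(n, covariates)
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G = panel.dosages
    sd = G.std(axis=0)
    X_r = _residualize(G, Q)
    xx = np.einsum("ij,ij->j", X_r, X_r)
    xy = X_r.T @ y_r
    df = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xx > 0, xy / np.where(xx > 0, xx, 1.0), np.nan)
        sse = y_r @ y_r - beta**2 * xx
        se = np.sqrt(np.maximum(sse, 0.0) / df / np.where(xx > 0, xx, np.nan))
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    scale = panel.dosage_scale
    out = panel.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    out["freq_a1"] = G.mean(axis=0) / scale
    out["beta"] = beta
    out["se"] = se
    out["z"] = t
    out["p"] = p
    out["n"] = n
    out["reason"] = ""
    mono = sd == 0
    out.loc[mono, ["beta", "se", "z", "p"]] = np.nan
    out.loc[mono, "reason"] = "monomorphic"
    return out


def _harmonize_row(ref_a1, ref_a2, a1, a2, beta, freq, ref_freq=None):
    """Align one study's alleles to the reference pair.

    Returns (beta, freq, ok).  A swap flips beta and freq; a strand flip is
    resolved through complements; palindromic pairs are resolved by allele
    frequency when both frequencies are informative (|freq - 0.5| > 0.2),
    else dropped.
    """
    if (a1, a2) == (ref_a1, ref_a2):
        return beta, freq, True
    if (a1, a2) == (ref_a2, ref_a1):
        return -beta, 1 - freq, True
    ca1, ca2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if ca1 is None or ca2 is None:
        return beta, freq, False
    palindromic = a1 == ca2 and {ca1, ca2} == {ref_a1, ref_a2}
    if palindromic:
        if ref_freq is None or abs(freq - 0.5) <= 0.2 or abs(ref_freq - 0.5) <= 0.2:
            return beta, freq, False
        if (freq > 0.5) == (ref_freq > 0.5):
            return beta, freq, True
        return -beta, 1 - freq, True
    if (ca1, ca2) == (ref_a1, ref_a2):
        return beta, freq, True
    if (ca1, ca2) == (ref_a2, ref_a1):
        return -beta, 1 - freq, True
    return beta, freq, False


def ivw_meta(
    tables: list[pd.DataFrame],
    n_filter_frac: float = 0.67,
    het_p_threshold: float = 1e-6,
    apply_filters: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-effects inverse-variance-weighted meta-analysis.

    Variants are keyed by (chrom, pos) with allele harmonization against the
    first cohort carrying the variant.  beta = sum(w_i b_i)/sum(w_i) with
    w_i = 1/se_i^2, se = (sum w_i)^(-1/2), p from the normal; Cochran's Q
    heterogeneity p on k-1 df.  Rows with meta sample size below
    ``n_filter_frac`` times the 90th percentile of N, or heterogeneity
    p below ``het_p_threshold``, are removed into the exclusion manifest.
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis requires at least two cohorts")
    rows, excluded = [], []
    keyed = [t.set_index(["chrom", "pos"]) for t in tables]
    all_keys = sorted(set().union(*[set(k.index) for k in keyed]))
    for key in all_keys:
        entries = []
        ref = None
        drop_reason = None
        for k in keyed:
            if key not in k.index:
                continue
            row = k.loc[key]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            if not np.isfinite(row["beta"]) or not np.isfinite(row["se"]):
                continue
            if ref is None:
                ref = row
                entries.append((row["beta"], row["se"], row["freq_a1"], row["n"]))
            else:
                b, f, ok = _harmonize_row(ref["a1"], ref["a2"], row["a1"], row["a2"],
                                          row["beta"], row["freq_a1"], ref["freq_a1"])
                if not ok:
                    drop_reason = "allele_mismatch"
                    continue
                entries.append((b, row["se"], f, row["n"]))
        if ref is None:
            continue
        b = np.array([e[0] for e in entries])
        se = np.array([e[1] for e in entries])
        w = 1.0 / se**2
        beta_meta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta_meta / se_meta
        k_stud = len(entries)
        if k_stud > 1:
            q = float(np.sum(w * (b - beta_meta) ** 2))
            q_p = float(stats.chi2.sf(q, k_stud - 1))
        else:
            q_p = np.nan
        rows.append({
            "chrom": key[0], "pos": key[1], "id": ref["id"], "a1": ref["a1"], "a2": ref["a2"],
            "freq_a1": float(np.mean([e[2] for e in entries])),
            "beta": beta_meta, "se": se_meta, "z": z,
            "p": 2 * stats.norm.sf(abs(z)),
            "n": float(np.sum([e[3] for e in entries])),
            "q_het_p": q_p, "k_studies": k_stud,
            "note": drop_reason or "",
        })
    meta = pd.DataFrame(rows)
    if meta.empty:
        return meta, pd.DataFrame()
    if apply_filters:
        n_cut = n_filter_frac * np.percentile(meta["n"], 90)
        low_n = meta["n"] < n_cut
        het = meta["q_het_p"].notna() & (meta["q_het_p"] < het_p_threshold)
        excluded_df = meta.loc[low_n | het].copy()
        excluded_df["reason"] = np.where(low_n[low_n | het], "low_n", "heterogeneity")
        meta = meta.loc[~(low_n | het)].reset_index(drop=True)
        if len(excluded_df):
            log.info("ivw_meta: excluded %d variants (%d low-N, %d heterogeneous)",
                     len(excluded_df), int(low_n.sum()), int(het.sum()))
        return meta, excluded_df.reset_index(drop=True)
    return meta, pd.DataFrame()


def _joint_fit(y, X, C):
    """OLS of y on [X, C]; returns beta, se, p for the X columns."""
    D = np.column_stack([X, C])
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    df = len(y) - rank
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))[: X.shape[1]]
    beta = coef[: X.shape[1]]
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def stepwise_conditional(
    sumstats: pd.DataFrame,
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates=None,
    window_kb: float = 10000,
    collinearity: float = 0.9,
    p_threshold: float = GENOME_WIDE_P,
    max_logp_increase: float = 2.0,
) -> pd.DataFrame:
    """Stepwise conditional selection of independent index variants.

    Iteratively picks the variant with the smallest conditional p (each
    candidate refit jointly with all previously selected variants within the
    window), skipping candidates with r^2 above the collinearity cutoff
    against any selected variant, until no conditional p clears the
    threshold.  Subsidiary signals whose conditional p exceeds their
    marginal p by more than ``max_logp_increase`` orders of magnitude are
    discarded.  Exact joint regression on the individual-level panel.
    """
    y = np.asarray(phenotype, dtype=float)
    C = _covariate_design(len(y), covariates)
    ss = sumstats.dropna(subset=["p"]).reset_index(drop=True)
    if ss.empty:
        return pd.DataFrame(columns=["id", "chrom", "pos", "beta", "se", "p",
                                     "beta_c", "se_c", "p_c"])
    idx_in_panel = np.array([panel.index_of(v) for v in ss["id"]])
    pos = ss["pos"].to_numpy()
    chrom = ss["chrom"].to_numpy()
    window = window_kb * 1000.0
    selected: list[int] = []  # positions into ss

    def conditional_stats(ci: int, sel: list[int]):
        near = [s for s in sel if chrom[s] == chrom[ci] and abs(pos[s] - pos[ci]) <= window]
        X = panel.dosages[:, idx_in_panel[[ci] + near]]
        beta, se, p = _joint_fit(y, X, C)
        return beta[0], se[0], p[0]

    while True:
        best = None
        for ci in range(len(ss)):
            if ci in selected:
                continue
            skip = False
            for s in selected:
                if chrom[s] == chrom[ci] and abs(pos[s] - pos[ci]) <= window:
                    r = panel.ld_r(idx_in_panel[ci], idx_in_panel[s])
                    if r**2 > collinearity:
                        skip = True
                        break
            if skip:
                continue
            b, se, p = conditional_stats(ci, selected)
            if p < p_threshold and (best is None or p < best[3]):
                best = (ci, b, se, p)
        if best is None:
            break
        selected.append(best[0])

    # final joint model per window-cluster; drop subsidiary signals whose
    # conditional p degraded by > max_logp_increase orders of magnitude
    changed = True
    while changed and selected:
        changed = False
        final = {}
        for ci in selected:
            b, se, p = conditional_stats(ci, [s for s in selected if s != ci])
            final[ci] = (b, se, p)
        order = sorted(selected, key=lambda s: ss["p"].iloc[s])
        for ci in order[1:]:
            p_marg = ss["p"].iloc[ci]
            p_cond = final[ci][2]
            if p_cond > p_marg * 10**max_logp_increase or p_cond >= p_threshold:
                selected.remove(ci)
                changed = True
                break
    rows = []
    for ci in selected:
        b, se, p = conditional_stats(ci, [s for s in selected if s != ci])
        rows.append({
            "id": ss["id"].iloc[ci], "chrom": chrom[ci], "pos": int(pos[ci]),
            "beta": ss["beta"].iloc[ci], "se": ss["se"].iloc[ci], "p": ss["p"].iloc[ci],
            "beta_c": b, "se_c": se, "p_c": p,
        })
    out = pd.DataFrame(rows)
    return out.sort_values("p").reset_index(drop=True) if len(out) else out


def clump_and_flag(
    index_variants: pd.DataFrame,
    panel: GenotypePanel,
    r2: float = 0.1,
    window_kb: float = 10000,
    known_list: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Greedy cross-trait LD clumping of index variants into loci.

    ``index_variants`` needs columns id, chrom, pos, p and optionally trait.
    Sorted by ascending p across traits, each unassigned variant seeds a
    locus absorbing every other index variant with r^2 > ``r2`` within the
    window.  A locus is novel unless some known-list variant (id or
    chrom/pos resolvable in the panel) clumps with one of its members under
    the same parameters.
    """
    iv = index_variants.reset_index(drop=True).sort_values("p")
    if "trait" not in iv.columns:
        iv = iv.assign(trait="trait")
    window = window_kb * 1000.0
    assigned: dict[int, int] = {}
    loci = []
    for i in iv.index:
        if i in assigned:
            continue
        locus_id = len(loci)
        members = [i]
        assigned[i] = locus_id
        gi = panel.index_of(iv.loc[i, "id"])
        for j in iv.index:
            if j in assigned:
                continue
            if iv.loc[j, "chrom"] != iv.loc[i, "chrom"]:
                continue
            if abs(iv.loc[j, "pos"] - iv.loc[i, "pos"]) > window:
                continue
            if panel.ld_r(gi, panel.index_of(iv.loc[j, "id"])) ** 2 > r2:
                assigned[j] = locus_id
                members.append(j)
        loci.append((locus_id, i, members))

    known_idx = []
    if known_list is not None and len(known_list):
        for _, krow in known_list.iterrows():
            try:
                if "id" in krow and pd.notna(krow.get("id")) and (panel.variants["id"] == krow["id"]).any():
                    known_idx.append(panel.index_of(krow["id"]))
                elif "pos" in krow:
                    m = panel.variants.index[
                        (panel.variants["chrom"] == krow.get("chrom")) & (panel.variants["pos"] == krow["pos"])
                    ]
                    if len(m):
                        known_idx.append(int(m[0]))
                    else:
                        raise KeyError
                else:
                    raise KeyError
            except KeyError:
                warnings.warn(f"known-list entry {dict(krow)} has no resolvable coordinates; ignored")

    rows = []
    for locus_id, lead, members in loci:
        novel = True
        for ki in known_idx:
            kpos = panel.variants["pos"].iloc[ki]
            kchrom = panel.variants["chrom"].iloc[ki]
            for m in members:
                if iv.loc[m, "chrom"] != kchrom or abs(iv.loc[m, "pos"] - kpos) > window:
                    continue
                if panel.ld_r(panel.index_of(iv.loc[m, "id"]), ki) ** 2 > r2:
                    novel = False
                    break
            if not novel:
                break
        member_df = iv.loc[members]
        rows.append({
            "locus_id": locus_id,
            "lead_id": iv.loc[lead, "id"],
            "lead_trait": iv.loc[lead, "trait"],
            "chrom": iv.loc[lead, "chrom"],
            "pos": int(iv.loc[lead, "pos"]),
            "p": iv.loc[lead, "p"],
            "traits": ",".join(sorted(member_df["trait"].unique())),
            "member_ids": ",".join(member_df["id"]),
            "n_members": len(members),
            "novel": novel,
        })
    return pd.DataFrame(rows)
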