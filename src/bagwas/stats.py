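"""Scalar statistics for cross-trait association and replication.

Covers: correlation recovered from a regression z-statistic, sex-difference
z-tests, one-sided binomial sign/replication tests, winner's-curse-corrected
replication power, Fisher exact annotation enrichment, and multiple-testing
adjustment (Bonferroni, Benjamini-Hochberg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-6


@dataclass
class AssocResult:
    beta: float
    se: float
    z: float
    n: int
    k: int  # number of covariates in the model


def r_from_z(res: AssocResult) -> float:
    """Standardized effect size from a regression z-statistic:
    r = sign(beta) * sqrt(z^2 / (z^2 + (n - k - 2)))."""
    dof = res.n - res.k - 2
    if dof <= 0:
        raise ValueError(f"n - k - 2 must be positive, got {dof}")
    r = math.sqrt(res.z**2 / (res.z**2 + dof))
    return math.copysign(r, res.beta) if res.beta != 0 else 0.0


@dataclass
class SexStratifiedEffect:
    beta_m: float
    se_m: float
    beta_f: float
    se_f: float


def sex_difference_test(e: SexStratifiedEffect) -> tuple[float, float]:
    """z = (beta_m - beta_f)/sqrt(se_m^2 + se_f^2), two-sided normal p."""
    if e.se_m <= 0 or e.se_f <= 0:
        raise ValueError("standard errors must be positive")
    z = (e.beta_m - e.beta_f) / math.sqrt(e.se_m**2 + e.se_f**2)
    return z, 2 * stats.norm.sf(abs(z))


def replication_tests(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Sign-concordance and nominal-replication binomial tests.

    ``records`` columns: beta_disc, beta_rep, p_rep (two-sided replication
    p).  concordant counts matching effect directions; its one-sided
    upper-tail binomial p uses p0 = 0.5.  replicated counts records whose
    one-tailed replication p in the discovery direction (p_rep/2 when the
    signs agree) is below ``alpha``; its binomial p uses p0 = alpha.
    """
    if len(records) == 0:
        raise ValueError("empty replication record list")
    n = len(records)
    sign_match = np.sign(records["beta_disc"].to_numpy()) == np.sign(records["beta_rep"].to_numpy())
    concordant = int(sign_match.sum())
    one_tailed = np.where(sign_match, records["p_rep"].to_numpy() / 2, 1 - records["p_rep"].to_numpy() / 2)
    replicated = int((one_tailed < alpha).sum())
    return {
        "n": n,
        "concordant": concordant,
        "p_sign": float(stats.binom.sf(concordant - 1, n, 0.5)),
        "replicated": replicated,
        "p_binom": float(stats.binom.sf(replicated - 1, n, alpha)),
    }


def winners_curse_z(z_obs: float, c: float) -> float:
    """Conditional-likelihood MLE of the true z given ascertainment |z| > c.

    The observed z was reported only because it cleared the two-sided
    selection threshold c, so the likelihood is the normal density truncated
    to |z| > c; the MLE shrinks |z| toward zero, the more the closer z sits
    to the threshold.
    """
    if c < 0:
        raise ValueError("threshold must be non-negative")
    sign = 1.0 if z_obs >= 0 else -1.0
    za = abs(z_obs)

    def nll(mu):
        denom = stats.norm.sf(c - mu) + stats.norm.cdf(-c - mu)
        return 0.5 * (za - mu) ** 2 + math.log(max(denom, 1e-300))

    res = optimize.minimize_scalar(nll, bounds=(-za - 5, za), method="bounded",
                                   options={"xatol": 1e-10})
    return sign * float(res.x)


def replication_power(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variant replication power with winner's-curse-corrected betas.

    ``records`` columns: beta_disc, se_disc, maf, n_rep, p_select (the
    two-sided discovery selection threshold, e.g. 5e-8 or 1e-6).  The
    discovery beta (standardized: per-allele effect on a unit-variance
    phenotype) is shrunk by the conditional-likelihood truncated-normal MLE
    at that variant's own threshold; the replication SE is
    1/sqrt(n_rep * 2 * maf * (1-maf)); one-tailed power at level ``alpha``
    is 1 - Phi(z_alpha - |beta_corrected|/se_rep).  The sum of powers is the
    expected number of nominal replications.
    """
    maf = records["maf"].to_numpy(dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    out = records.copy()
    z_alpha = stats.norm.isf(alpha)
    betas_c, powers = [], []
    for _, r in records.iterrows():
        c = stats.norm.isf(r["p_select"] / 2)
        z_obs = r["beta_disc"] / r["se_disc"]
        z_corr = winners_curse_z(z_obs, c)
        beta_corr = z_corr * r["se_disc"]
        se_rep = 1.0 / math.sqrt(r["n_rep"] * 2 * r["maf"] * (1 - r["maf"]))
        powers.append(float(stats.norm.sf(z_alpha - abs(beta_corr) / se_rep)))
        betas_c.append(beta_corr)
    out["beta_corrected"] = betas_c
    out["power"] = powers
    out.attrs["expected_replications"] = float(np.sum(powers))
    return out


def fisher_annotation_enrichment(
    candidate_counts: dict[str, int] | pd.Series,
    reference_counts: dict[str, int] | pd.Series,
) -> pd.DataFrame:
    """Two-tailed Fisher exact test per annotation on the 2x2 table
    (candidate with/without annotation vs reference with/without).

    Annotations may multi-count (a variant with several annotations
    contributes to each), so totals are sums over annotations.  Zero cells
    flag the odds ratio infinite/zero; the exact p remains finite.
    """
    cand = pd.Series(candidate_counts, dtype=float)
    ref = pd.Series(reference_counts, dtype=float)
    if (cand < 0).any() or (ref < 0).any():
        raise ValueError("counts must be non-negative")
    n_cand, n_ref = cand.sum(), ref.sum()
    if n_cand == 0:
        raise ValueError("candidate total is zero")
    rows = []
    for ann in sorted(set(cand.index) | set(ref.index)):
        a = int(cand.get(ann, 0))
        b = int(n_cand - a)
        c = int(ref.get(ann, 0))
        d = int(n_ref - c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if b == 0 or c == 0:
            orv, flag = math.inf, "infinite"
        elif a == 0 or d == 0:
            orv, flag = 0.0, "zero"
        else:
            orv, flag = (a * d) / (b * c), ""
        rows.append({"annotation": ann, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": orv, "p": float(p), "or_flag": flag})
    return pd.DataFrame(rows)


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Bonferroni (capped at 1) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")
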