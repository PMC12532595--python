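"""Multi-instrument summary-data Mendelian randomization (GSMR-style) and
clumping + p-thresholding polygenic scores.

MR integrates per-instrument ratio estimates beta_zy/beta_zx by generalized
least squares with an LD-aware covariance, after HEIDI-outlier removal of
instruments whose ratio deviates from the top instrument's (pleiotropy
screen).  PGS builds scores over p-value-thresholded, LD-clumped training
summary statistics and evaluates them by partial correlation with the
target phenotype given covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .syndata import GenotypePanel

DEFAULT_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


def standardize_effects(z, allele_freq, n):
    """Per-SD instrument effects from z, allele frequency and sample size:
    beta_sd = z / sqrt(2 p (1-p) (n + z^2)); se_sd = beta_sd / z (z != 0),
    else 1/sqrt(2 p (1-p) n)."""
    z = np.asarray(z, dtype=float)
    p = np.asarray(allele_freq, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must lie in (0, 1)")
    het = 2 * p * (1 - p)
    beta_sd = z / np.sqrt(het * (n + z**2))
    se_sd = np.where(z != 0, np.abs(beta_sd / np.where(z != 0, z, 1.0)),
                     1.0 / np.sqrt(het * n))
    return beta_sd, se_sd


def _harmonize_ma(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Merge two .ma tables on SNP, flipping the outcome effect when its
    effect allele is the exposure's other allele."""
    m = exposure.merge(outcome, on="SNP", suffixes=("_x", "_y"))
    same = (m["A1_x"] == m["A1_y"]) & (m["A2_x"] == m["A2_y"])
    swap = (m["A1_x"] == m["A2_y"]) & (m["A2_x"] == m["A1_y"])
    m = m[same | swap].copy()
    flip = swap[same | swap]
    m.loc[flip, "b_y"] = -m.loc[flip, "b_y"]
    m.loc[flip, "freq_y"] = 1 - m.loc[flip, "freq_y"]
    return m


def _greedy_clump(df: pd.DataFrame, panel: GenotypePanel, r2: float, window_kb: float) -> list[int]:
    """Greedy p-ascending clumping; returns retained row indices."""
    pos = panel.variants.set_index("id")["pos"]
    chrom = panel.variants.set_index("id")["chrom"]
    order = df.sort_values("p").index
    kept: list[int] = []
    window = window_kb * 1000.0
    for i in order:
        vi = df.loc[i, "SNP"]
        ok = True
        for j in kept:
            vj = df.loc[j, "SNP"]
            if chrom[vi] != chrom[vj] or abs(pos[vi] - pos[vj]) > window:
                continue
            if panel.ld_r(panel.index_of(vi), panel.index_of(vj)) ** 2 >= r2:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


@dataclass
class MrEstimate:
    b_xy: float
    se: float
    p: float
    n_instruments_used: int
    outliers_removed: list[tuple[str, float]] = field(default_factory=list)


def gsmr(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    panel: GenotypePanel,
    p_select: float = 5e-8,
    clump_r2: float = 0.001,
    window_kb: float = 10000,
    heidi_p: float = 0.01,
    min_instruments: int = 10,
    ld_prune_r: float = 0.05,
) -> MrEstimate:
    """GLS combination of instrument ratio estimates with HEIDI outlier
    removal.

    Instruments are exposure variants with p < ``p_select`` surviving
    ``clump_r2`` clumping.  Per instrument, b_i = beta_zy/beta_zx with
    var(b_i) = (se_zy^2 + b_i^2 se_zx^2)/beta_zx^2; the GLS covariance uses
    instrument LD (near-diagonal after clumping).  Outliers deviate from the
    top (smallest exposure p) instrument's ratio at HEIDI p < ``heidi_p``
    and are removed before refitting; the reverse direction is obtained by
    swapping the roles of the two tables.
    """
    m = _harmonize_ma(exposure_stats, outcome_stats)
    m = m[m["p_x"] < p_select].reset_index(drop=True)
    kept = _greedy_clump(m.rename(columns={"p_x": "p"}), panel, clump_r2, window_kb)
    m = m.loc[kept].reset_index(drop=True)
    if len(m) < min_instruments:
        raise ValueError(
            f"only {len(m)} instruments after selection and clumping; floor is {min_instruments}"
        )

    def _ratios(frame):
        bzx = frame["b_x"].to_numpy()
        b = frame["b_y"].to_numpy() / bzx
        # plug-in ratio variance: a first pass with outcome-only weights
        # gives the pooled estimate entering the exposure-error term, so the
        # weights do not share noise with the individual ratios
        w0 = bzx**2 / frame["se_y"].to_numpy() ** 2
        bhat = float(np.sum(w0 * b) / np.sum(w0))
        sezx = frame["se_x"].to_numpy()
        var_b = (frame["se_y"].to_numpy() ** 2 + bhat**2 * sezx**2) / bzx**2
        # second-order weak-instrument term of the ratio variance
        var_b = var_b * (1.0 + 3.0 * (sezx / bzx) ** 2)
        return b, var_b

    outliers: list[tuple[str, float]] = []
    while True:
        b, var_b = _ratios(m)
        # HEIDI-style outlier screen: each instrument's ratio against the
        # leave-one-out inverse-variance estimate (anchoring on a single
        # instrument would inject that instrument's own noise); instruments
        # are independent after clumping, so var(d_i) = var(b_i) + var(loo_i)
        removed = False
        if len(m) > min_instruments:
            w = 1.0 / var_b
            sw, swb = w.sum(), (w * b).sum()
            # trim only when the instrument set shows global heterogeneity:
            # removing apparent outliers from a homogeneous set distorts the
            # sampling distribution of the estimate
            q = float(np.sum(w * (b - swb / sw) ** 2))
            q_p = float(stats.chi2.sf(q, len(b) - 1))
            if q_p < 0.05:
                loo = (swb - w * b) / (sw - w)
                var_loo = 1.0 / (sw - w)
                d = b - loo
                z_d = d / np.sqrt(var_b + var_loo)
                p_d = 2 * stats.norm.sf(np.abs(z_d))
                worst = int(np.argmin(p_d))
                if p_d[worst] < heidi_p:
                    outliers.append((m.loc[worst, "SNP"], float(p_d[worst])))
                    m = m.drop(index=worst).reset_index(drop=True)
                    removed = True
        if not removed:
            break

    b, var_b = _ratios(m)
    idx = np.array([panel.index_of(v) for v in m["SNP"]])
    R = panel.ld_matrix(idx)
    # after r2 < 0.001 clumping, residual off-diagonal LD is reference-panel
    # sampling noise; shrink it to zero so the GLS does not fit noise
    R = np.where(np.abs(R) < ld_prune_r, 0.0, R)
    np.fill_diagonal(R, 1.0)
    sd = np.sqrt(var_b)
    V = R * np.outer(sd, sd)
    one = np.ones(len(b))
    try:
        Vi_b = np.linalg.solve(V, b)
        Vi_1 = np.linalg.solve(V, one)
    except np.linalg.LinAlgError:
        Vi = np.linalg.pinv(V)
        Vi_b, Vi_1 = Vi @ b, Vi @ one
    denom = one @ Vi_1
    b_xy = float((one @ Vi_b) / denom)
    se = float(denom**-0.5)
    z = b_xy / se
    return MrEstimate(b_xy=b_xy, se=se, p=float(2 * stats.norm.sf(abs(z))),
                      n_instruments_used=len(b), outliers_removed=outliers)


def partial_correlation(x: np.ndarray, y: np.ndarray, covariates) -> float:
    """Pearson correlation of x and y after residualizing both on the
    covariates (with intercept); equals the partial correlation."""
    n = len(x)
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    xr = x - Q @ (Q.T @ x)
    yr = y - Q @ (Q.T @ y)
    return float(np.dot(xr, yr) / math.sqrt(np.dot(xr, xr) * np.dot(yr, yr)))


@dataclass
class PgsResult:
    table: pd.DataFrame  # threshold, n_variants, partial_r, partial_r2
    scores: dict[float, np.ndarray]
    best_threshold: float

    @property
    def best_partial_r2(self) -> float:
        return float(self.table.set_index("threshold").loc[self.best_threshold, "partial_r2"])


def cp_pgs(
    training_sumstats: pd.DataFrame,
    target_panel: GenotypePanel,
    target_phenotype: np.ndarray,
    covariates,
    training_ids: set[str] | None = None,
    target_ids: set[str] | None = None,
    clump_r2: float = 0.1,
    window_kb: float = 500,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> PgsResult:
    """Clumping + p-thresholding polygenic scores.

    Training summary statistics (.ma columns) are p-informed clumped at
    ``clump_r2`` within ``window_kb`` using the target panel as LD
    reference; for each threshold the score is sum(beta * dosage) over
    retained variants with p below it (variant sets therefore nest across
    thresholds).  Evaluation is the partial correlation of score and
    phenotype given the covariates; training and target samples must be
    disjoint when identifier sets are provided.
    """
    if training_ids is not None and target_ids is not None:
        overlap = set(training_ids) & set(target_ids)
        if overlap:
            raise ValueError(f"{len(overlap)} individuals overlap between training and target")
    ss = training_sumstats[training_sumstats["SNP"].isin(set(target_panel.variants["id"]))].reset_index(drop=True)
    kept = _greedy_clump(ss.rename(columns={"p": "p"}), target_panel, clump_r2, window_kb)
    ss = ss.loc[kept].reset_index(drop=True)
    pv = target_panel.variants.set_index("id")
    idx = np.array([target_panel.index_of(v) for v in ss["SNP"]])
    beta = ss["b"].to_numpy(dtype=float).copy()
    flip = pv.loc[ss["SNP"], "a1"].to_numpy() != ss["A1"].to_numpy()
    beta[flip] = -beta[flip]
    y = np.asarray(target_phenotype, dtype=float)
    rows, scores = [], {}
    for thr in sorted(thresholds):
        sel = ss["p"].to_numpy() < thr if thr < 1.0 else np.ones(len(ss), dtype=bool)
        score = target_panel.dosages[:, idx[sel]] @ beta[sel] if sel.any() else np.zeros(len(y))
        if sel.any() and score.std() > 0:
            pr = partial_correlation(score, y, covariates)
        else:
            pr = 0.0
        scores[thr] = score
        rows.append({"threshold": thr, "n_variants": int(sel.sum()),
                     "partial_r": pr, "partial_r2": pr**2})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["partial_r2"].idxmax(), "threshold"])
    return PgsResult(table=table, scores=scores, best_threshold=best)
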