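"""Stacked cross-prediction age estimation and brain-age-gap computation.

The workflow mirrors the standard brain-age pipeline: per tissue class
(gray/white matter), PCA-reduced imaging features feed an ensemble of
learners evaluated by k-fold cross-prediction with repeats, so every
individual is predicted only by models that never saw them.  Learner
predictions are stacked within tissue by a linear meta-model fitted on
nested out-of-fold predictions, the two tissue-level predictions are stacked
again into a combined estimate, and repeat-level estimates are averaged.
BAG = predicted age - chronological age; because of regression dilution the
raw gap is age-dependent, which is removed by residualizing on (or
covarying for) age, age^2, sex, site and TIV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, Ridge

log = logging.getLogger(__name__)


def default_learners() -> list[tuple[str, object]]:
    """Desk-scale learner roster: a ridge linear model and gradient-boosted
    trees, standing in for the heavier RVM / boosted ensembles used at full
    scale.  Entries are (name, unfitted estimator); estimators are cloned
    per fold."""
    from xgboost import XGBRegressor

    return [
        ("ridge", Ridge(alpha=1.0)),
        ("gbt", XGBRegressor(n_estimators=100, learning_rate=0.1, max_depth=3,
                             n_jobs=1, random_state=0, verbosity=0)),
    ]


@dataclass
class CrossPredictionPlan:
    """Cross-prediction protocol: folds, repeats, PCA size and learners."""

    n_folds: int = 10
    n_repeats: int = 5
    n_components: int = 50
    learners: list[tuple[str, object]] | None = None
    stacking_folds: int = 10
    seed: int = 0

    def resolved_learners(self) -> list[tuple[str, object]]:
        return self.learners if self.learners is not None else default_learners()


@dataclass
class OofPredictions:
    """Out-of-fold prediction tensor (individual x tissue x learner x repeat)."""

    tensor: np.ndarray
    tissues: list[str]
    learner_names: list[str]
    plan: CrossPredictionPlan

    @property
    def estimates_per_individual(self) -> int:
        _, t, l, r = self.tensor.shape
        return t * l * r


@dataclass
class StackedAgeEstimate:
    """Stacked predictions per tissue and combined, averaged over repeats."""

    per_tissue: dict[str, np.ndarray]
    pred_combined: np.ndarray | None
    tissue_repeat: np.ndarray  # (n, n_tissues, n_repeats)
    combined_repeat: np.ndarray | None
    oof: OofPredictions


def assign_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded permutation into folds as equal as possible; the remainder is
    distributed to the first folds.  Each individual lands in exactly one
    test fold."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError(f"fewer individuals ({n}) than folds ({n_folds})")
    perm = rng.permutation(n)
    base, rem = divmod(n, n_folds)
    sizes = [base + (1 if f < rem else 0) for f in range(n_folds)]
    folds = np.empty(n, dtype=int)
    start = 0
    for f, s in enumerate(sizes):
        folds[perm[start:start + s]] = f
        start += s
    return folds


def crosspredict_ensemble(
    features_by_tissue: dict[str, np.ndarray],
    age: np.ndarray,
    plan: CrossPredictionPlan,
) -> OofPredictions:
    """Out-of-fold ensemble predictions with PCA fitted on training folds only.

    For each repeat a fresh fold assignment is drawn; within each fold the
    PCA transform and every learner are fitted on the training folds and
    applied to the held-out fold, so each (individual, repeat) cell is
    predicted exactly once by models trained without that individual.
    """
    age = np.asarray(age, dtype=float)
    n = age.shape[0]
    tissues = list(features_by_tissue)
    for t in tissues:
        F = features_by_tissue[t]
        if F.shape[0] != n:
            raise ValueError(f"features for tissue {t!r} not row-aligned with age")
        if not np.isfinite(F).all():
            raise ValueError(f"missing values in features for tissue {t!r}")
    learners = plan.resolved_learners()
    tensor = np.full((n, len(tissues), len(learners), plan.n_repeats), np.nan)
    for r in range(plan.n_repeats):
        rng = np.random.default_rng([plan.seed, r])
        folds = assign_folds(n, plan.n_folds, rng)
        for ti, t in enumerate(tissues):
            F = features_by_tissue[t]
            for f in range(plan.n_folds):
                test = folds == f
                train = ~test
                ncomp = min(plan.n_components, int(train.sum()) - 1, F.shape[1])
                pca = PCA(n_components=ncomp, random_state=0)
                Xtr = pca.fit_transform(F[train])
                Xte = pca.transform(F[test])
                for li, (_, est) in enumerate(learners):
                    model = clone(est)
                    model.fit(Xtr, age[train])
                    tensor[test, ti, li, r] = model.predict(Xte)
    assert np.isfinite(tensor).all()
    return OofPredictions(tensor=tensor, tissues=tissues,
                          learner_names=[nm for nm, _ in learners], plan=plan)


def _nested_stack(X: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Out-of-fold predictions of a linear meta-model combining columns of X."""
    if X.shape[1] == 1:
        return X[:, 0].copy()
    n = X.shape[0]
    folds = assign_folds(n, n_folds, rng)
    out = np.empty(n)
    for f in range(n_folds):
        test = folds == f
        meta = LinearRegression()
        meta.fit(X[~test], y[~test])
        out[test] = meta.predict(X[test])
    return out


def stack_predictions(oof: OofPredictions, age: np.ndarray, plan: CrossPredictionPlan | None = None) -> StackedAgeEstimate:
    """Stack learners within tissue, then tissues into a combined estimate.

    A single learner passes through unchanged (meta-weight one); the
    combined estimate requires at least two tissues.  Repeat-level stacked
    estimates are averaged into one value per tissue trait per individual.
    """
    plan = plan or oof.plan
    age = np.asarray(age, dtype=float)
    n, n_tissues, n_learners, n_repeats = oof.tensor.shape
    tissue_repeat = np.empty((n, n_tissues, n_repeats))
    for r in range(n_repeats):
        for ti in range(n_tissues):
            rng = np.random.default_rng([plan.seed, 1000 + r, ti])
            tissue_repeat[:, ti, r] = _nested_stack(oof.tensor[:, ti, :, r], age, plan.stacking_folds, rng)
    combined_repeat = None
    if n_tissues >= 2:
        combined_repeat = np.empty((n, n_repeats))
        for r in range(n_repeats):
            rng = np.random.default_rng([plan.seed, 2000 + r])
            combined_repeat[:, r] = _nested_stack(tissue_repeat[:, :, r], age, plan.stacking_folds, rng)
    per_tissue = {t: tissue_repeat[:, ti, :].mean(axis=1) for ti, t in enumerate(oof.tissues)}
    return StackedAgeEstimate(
        per_tissue=per_tissue,
        pred_combined=combined_repeat.mean(axis=1) if combined_repeat is not None else None,
        tissue_repeat=tissue_repeat,
        combined_repeat=combined_repeat,
        oof=oof,
    )


def combined_estimate(est: StackedAgeEstimate) -> np.ndarray:
    if est.pred_combined is None:
        raise ValueError("combined estimate requires at least two tissues")
    return est.pred_combined


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = covariates.to_numpy(dtype=float)
    return np.column_stack([np.ones(X.shape[0]), X])


def compute_bag(
    predictions: dict[str, np.ndarray] | np.ndarray,
    age: np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Raw and covariate-adjusted BAG per tissue trait.

    bag_raw = prediction - age; bag_adj is the OLS residual of bag_raw on
    the covariates (intercept included), which removes the regression-
    dilution age dependence.  Individuals with missing covariates are
    dropped with a logged count.
    """
    if isinstance(predictions, np.ndarray):
        predictions = {"trait": predictions}
    age = np.asarray(age, dtype=float)
    keep = ~covariates.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("compute_bag: dropped %d individuals with missing covariates", n_dropped)
    X = _design(covariates.loc[keep])
    frames = []
    for trait, pred in predictions.items():
        raw = np.asarray(pred, dtype=float)[keep] - age[keep]
        coef, *_ = np.linalg.lstsq(X, raw, rcond=None)
        adj = raw - X @ coef
        frames.append(pd.DataFrame({
            "individual": np.where(keep)[0],
            "trait": trait,
            "bag_raw": raw,
            "bag_adj": adj,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["covariates"] = list(covariates.columns)
    return out


@dataclass
class ModelMetrics:
    r: float
    r2: float
    mae: float
    icc: float | None = None


def icc_c1(test: np.ndarray, retest: np.ndarray) -> float:
    """ICC(C,1): two-way mixed-effects, consistency, single measurement.

    From the two-way ANOVA of an n x k (k = 2 sessions) table:
    ICC = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err).
    """
    data = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def model_metrics(pred: np.ndarray, age: np.ndarray, retest_pred: np.ndarray | None = None,
                  retest_ref: np.ndarray | None = None) -> ModelMetrics:
    """r, R^2 = 1 - SS_res/SS_tot (no refit), MAE, and optionally ICC(C,1).

    If ``retest_pred`` is given, ICC is computed between ``retest_ref``
    (default: ``pred``) and ``retest_pred``; both must be aligned vectors
    over the retest subset.  R^2 here is not the square of r: a biased or
    miscalibrated predictor can make it negative.
    """
    pred = np.asarray(pred, float)
    age = np.asarray(age, float)
    if pred.shape != age.shape:
        raise ValueError("pred and age must have the same length")
    ss_res = np.sum((age - pred) ** 2)
    ss_tot = np.sum((age - age.mean()) ** 2)
    icc = None
    if retest_pred is not None:
        ref = pred if retest_ref is None else np.asarray(retest_ref, float)
        if len(ref) != len(retest_pred):
            raise ValueError("retest vectors must be aligned")
        icc = icc_c1(ref, retest_pred)
    return ModelMetrics(
        r=float(stats.pearsonr(pred, age)[0]) if pred.std() > 0 else 0.0,
        r2=float(1 - ss_res / ss_tot),
        mae=float(np.mean(np.abs(pred - age))),
        icc=icc,
    )
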