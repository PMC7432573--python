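"""Transformed-age elastic-net clock.

Chronological age is first mapped through a piecewise log-linear transform
that is logarithmic up to an adult-age pivot (default 20 years) and linear
beyond it — children's methylomes change much faster than adults', and the
transform makes the methylation-age relationship approximately linear over
the whole lifespan. The transformed age is then regressed on the CpG
beta-values with an elastic net (mixing weight alpha, default 0.5; penalty
strength lambda chosen by k-fold cross-validation), which performs the
automatic CpG selection that defines the clock. Accuracy is estimated by
leave-one-dataset-out cross-validation: each cohort in turn is held out
entirely, the clock is trained on the remaining cohorts and evaluated on the
held-out one, so the estimate reflects transfer to genuinely new datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .acceleration import compute_aa, summarize_accuracy
from .data import ClockModel, MethylationDataset, SampleSheet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Age transform
# ---------------------------------------------------------------------------

def transform_age(age, adult_age: float = 20.0):
    """Piecewise log-linear age transform.

    log((age+1)/(adult_age+1)) for age <= adult_age, and
    (age - adult_age)/(adult_age+1) beyond; continuous and strictly
    increasing, zero at the pivot.
    """
    a = np.asarray(age, dtype=float)
    if (a < 0).any():
        raise ValueError("age must be non-negative")
    out = np.where(
        a <= adult_age,
        np.log((a + 1) / (adult_age + 1)),
        (a - adult_age) / (adult_age + 1),
    )
    return float(out) if out.ndim == 0 else out


def inverse_transform_age(t, adult_age: float = 20.0):
    """Inverse of :func:`transform_age` (defined for all real t)."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= 0,
        (adult_age + 1) * np.exp(t) - 1,
        (adult_age + 1) * t + adult_age,
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

@dataclass
class ClockTrainConfig:
    """Training hyper-parameters for the clock."""

    alpha: float = 0.5          # elastic-net mixing weight (1 = lasso)
    n_folds: int = 10           # CV folds for the penalty path
    lambda_rule: str = "min"    # "min" or "1se"
    adult_age: float = 20.0
    standardize: bool = True
    seed: int = 0
    n_lambdas: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


def _stratified_folds(groups: np.ndarray, n_folds: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Fold assignment spreading every group's samples across folds, so no
    fold coincides with a single dataset."""
    fold = np.empty(len(groups), dtype=int)
    offset = 0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)
    return fold


class MuscleAgeClock(RegressorMixin, BaseEstimator):
    """Elastic-net regression of transformed age on CpG beta-values.

    sklearn-style estimator: ``fit(X, y)`` with X of shape
    (n_samples, n_probes) and y chronological ages in years; ``predict``
    returns ages in years (inverse-transformed, clipped at 0). Pass
    ``groups`` (dataset labels) to ``fit`` to stratify the internal CV folds
    across datasets.

    Attributes after fit: ``intercept_``, ``coef_`` (on the original beta
    scale), ``lambda_`` (selected penalty), ``n_nonzero_``,
    ``feature_names_in_`` when X is a DataFrame.
    """

    def __init__(self, alpha: float = 0.5, n_folds: int = 10,
                 lambda_rule: str = "min", adult_age: float = 20.0,
                 standardize: bool = True, seed: int = 0, n_lambdas: int = 50,
                 max_iter: int = 5000, tol: float = 1e-4):
        self.alpha = alpha
        self.n_folds = n_folds
        self.lambda_rule = lambda_rule
        self.adult_age = adult_age
        self.standardize = standardize
        self.seed = seed
        self.n_lambdas = n_lambdas
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, groups=None) -> "MuscleAgeClock":
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise ValueError("training ages must all be known")
        if np.ptp(y) == 0:
            raise ValueError("cannot fit clock on constant age")
        ty = transform_age(y, self.adult_age)

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        Z = (X - mu) / sd

        rng = np.random.default_rng(self.seed)
        if groups is not None:
            fold = _stratified_folds(np.asarray(groups), self.n_folds, rng)
        else:
            fold = rng.permutation(len(y)) % self.n_folds
        cv = [(np.flatnonzero(fold != k), np.flatnonzero(fold == k))
              for k in range(self.n_folds)]

        l1_ratio = max(self.alpha, 1e-6)  # sklearn disallows pure-ridge CV path at 0
        cv_model = ElasticNetCV(
            l1_ratio=l1_ratio, alphas=self.n_lambdas, cv=cv,
            max_iter=self.max_iter, tol=self.tol, selection="cyclic",
        )
        cv_model.fit(Z, ty)

        mse = cv_model.mse_path_.mean(axis=1)
        se = cv_model.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_model.mse_path_.shape[1])
        alphas = cv_model.alphas_  # descending
        i_min = int(np.argmin(mse))
        if self.lambda_rule == "min":
            lam = float(cv_model.alpha_)
            coef_std, icept_std = cv_model.coef_, float(cv_model.intercept_)
        else:  # "1se": largest penalty within one SE of the minimum
            ok = np.flatnonzero(mse <= mse[i_min] + se[i_min])
            lam = float(alphas[ok[0]])
            refit = ElasticNet(alpha=lam, l1_ratio=l1_ratio,
                               max_iter=self.max_iter, tol=self.tol)
            refit.fit(Z, ty)
            coef_std, icept_std = refit.coef_, float(refit.intercept_)

        self.coef_ = coef_std / sd
        self.intercept_ = icept_std - float((coef_std * mu / sd).sum())
        self.lambda_ = lam
        self.lambda_path_ = alphas
        self.cv_mse_ = mse
        self.n_nonzero_ = int(np.count_nonzero(self.coef_))
        logger.info("clock fit: lambda=%.5g (%s rule), %d nonzero of %d probes",
                    lam, self.lambda_rule, self.n_nonzero_, X.shape[1])
        return self

    def predict(self, X) -> np.ndarray:
        if hasattr(X, "to_numpy"):
            X = X.to_numpy(dtype=float)
        t = self.intercept_ + np.asarray(X, dtype=float) @ self.coef_
        return np.maximum(inverse_transform_age(t, self.adult_age), 0.0)


# ---------------------------------------------------------------------------
# Dataset-level wrappers
# ---------------------------------------------------------------------------

def _stack_training(datasets: Sequence[MethylationDataset],
                    sheets: Sequence[SampleSheet]):
    """Stack datasets into one samples x probes matrix with ages and groups.
    All datasets must share one probe set (order of the first is used)."""
    probes = datasets[0].probe_ids
    for ds in datasets[1:]:
        if set(ds.probe_ids) != set(probes):
            raise ValueError(f"probe set mismatch: dataset {ds.dataset_id} differs")
    Xs, ages, groups, sample_ids = [], [], [], []
    for ds, sheet in zip(datasets, sheets):
        aligned = sheet.aligned_to(ds.sample_ids)
        a = aligned.ages()
        if np.isnan(a).any():
            raise ValueError(f"dataset {ds.dataset_id} has samples without age")
        Xs.append(ds.restrict_probes(probes).beta.to_numpy(dtype=float).T)
        ages.append(a)
        groups.extend([ds.dataset_id] * ds.n_samples)
        sample_ids.extend(ds.sample_ids)
    X = pd.DataFrame(np.vstack(Xs), index=sample_ids, columns=probes)
    return X, np.concatenate(ages), np.asarray(groups)


def train_clock(
    datasets: Sequence[MethylationDataset],
    sheets: Sequence[SampleSheet],
    cfg: ClockTrainConfig | None = None,
    gold_profile: dict[str, float] | pd.Series | None = None,
    gold_standard_id: str = "",
) -> ClockModel:
    """Train the clock on calibrated datasets sharing one probe set.

    ``gold_profile`` (probe -> mean beta of the gold standard) supplies the
    fallback values used at prediction time when a query dataset lacks some
    model probes; when omitted, the training-data mean profile is used.
    """
    cfg = cfg or ClockTrainConfig()
    X, ages, groups = _stack_training(datasets, sheets)
    est = MuscleAgeClock(alpha=cfg.alpha, n_folds=cfg.n_folds,
                         lambda_rule=cfg.lambda_rule, adult_age=cfg.adult_age,
                         standardize=cfg.standardize, seed=cfg.seed,
                         n_lambdas=cfg.n_lambdas)
    est.fit(X, ages, groups=groups)

    nz = np.flatnonzero(est.coef_)
    weights = {str(X.columns[j]): float(est.coef_[j]) for j in nz}
    if gold_profile is None:
        profile = X.mean(axis=0)
    else:
        profile = pd.Series(gold_profile, dtype=float)
    gold = {pid: float(profile[pid]) for pid in weights}
    return ClockModel(
        intercept=float(est.intercept_), weights=weights,
        adult_age=cfg.adult_age, alpha=cfg.alpha, lambda_=est.lambda_,
        gold_standard_id=gold_standard_id, gold_profile=gold,
    )


def predict_age(model: ClockModel, ds: MethylationDataset,
                max_missing_fraction: float = 0.05) -> pd.Series:
    """Predict ages (years) for every sample of ``ds``.

    Model probes absent from the dataset are imputed from the gold-standard
    profile; more than ``max_missing_fraction`` of them missing is an error.
    """
    probes = model.probe_ids
    missing = [p for p in probes if p not in ds.beta.index]
    if probes and len(missing) > max_missing_fraction * len(probes):
        raise ValueError(
            f"{len(missing)}/{len(probes)} model probes absent from dataset "
            f"{ds.dataset_id}: {missing[:10]}..."
        )
    X = np.empty((ds.n_samples, len(probes)))
    for j, pid in enumerate(probes):
        if pid in ds.beta.index:
            X[:, j] = ds.beta.loc[pid].to_numpy(dtype=float)
        else:
            X[:, j] = model.gold_profile[pid]
    w = np.array([model.weights[p] for p in probes])
    t = model.intercept + (X @ w if len(probes) else 0.0)
    pred = np.maximum(inverse_transform_age(np.atleast_1d(t), model.adult_age), 0.0)
    if not len(probes):
        pred = np.full(ds.n_samples, max(inverse_transform_age(model.intercept,
                                                               model.adult_age), 0.0))
    return pd.Series(pred, index=ds.sample_ids, name="predicted_age")


def loocv(
    datasets: Sequence[MethylationDataset],
    sheets: Sequence[SampleSheet],
    cfg: ClockTrainConfig | None = None,
    gold_profile: dict[str, float] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-dataset-out cross-validation.

    For each dataset, a clock is trained on all the others and evaluated on
    the held-out one. Returns the pooled per-sample acceleration table and a
    per-dataset summary (n, Pearson r where computable, median |AA_diff|,
    mean AA_diff, median |AA_resid|).
    """
    if len(datasets) < 3:
        raise ValueError("leave-one-dataset-out CV needs at least 3 datasets")
    cfg = cfg or ClockTrainConfig()
    tables = []
    for i, (held, held_sheet) in enumerate(zip(datasets, sheets)):
        train_ds = [d for j, d in enumerate(datasets) if j != i]
        train_sheets = [s for j, s in enumerate(sheets) if j != i]
        model = train_clock(train_ds, train_sheets, cfg, gold_profile)
        pred = predict_age(model, held)
        actual = held_sheet.aligned_to(held.sample_ids).ages()
        tables.append(compute_aa(pred.to_numpy(), actual,
                                 group_ids=[held.dataset_id] * held.n_samples,
                                 sample_ids=list(held.sample_ids)))
        logger.info("LOOCV %d/%d: held out %s (n=%d)", i + 1, len(datasets),
                    held.dataset_id, held.n_samples)
    table = pd.concat(tables, ignore_index=True)
    summary = summarize_accuracy(table)
    return table, summary
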