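"""Array preprocessing: QC filters, beta/M conversion, imputation, batch
adjustment, cross-dataset probe intersection.

The filters follow standard Illumina-array practice: samples are screened on
their detection p-value failure fraction, then probes on detection p-values,
bead counts, probe class (non-CpG, multimapping, SNP-associated) and sex
chromosomes. Thresholds use the conventional strict/inclusive semantics
(sample removed when *more than* 10% of probes fail; bead-count rule applies
from 5% of samples *inclusive*).

Batch adjustment is a parametric empirical-Bayes location-scale correction on
M-values: per-probe standardization, per-batch mean/variance estimates shrunk
toward across-probe priors (normal for means, inverse-gamma for variances),
then removal of the batch effects and de-standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

from .data import MethylationDataset, ProbeAnnotation

logger = logging.getLogger(__name__)

#: logit clipping bound for the beta -> M conversion
EPS = 1e-6


@dataclass
class DetectionInfo:
    """Per-call detection p-values and (optionally) bead counts, aligned to a
    beta matrix (probes x samples)."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        p = self.detection_p.to_numpy(dtype=float)
        if np.nanmin(p) < 0 or np.nanmax(p) > 1:
            raise ValueError("detection p-values outside [0, 1]")
        if self.bead_count is not None:
            if (self.bead_count.to_numpy() < 0).any():
                raise ValueError("negative bead count")

    def aligned_to(self, ds: MethylationDataset) -> "DetectionInfo":
        p = self.detection_p.reindex(index=ds.probe_ids, columns=ds.sample_ids)
        if p.isna().any().any():
            raise ValueError("detection info does not cover the dataset")
        b = None
        if self.bead_count is not None:
            b = self.bead_count.reindex(index=ds.probe_ids, columns=ds.sample_ids)
        return DetectionInfo(p, b)


@dataclass
class QCReport:
    """What a QC step removed or measured, and why."""

    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    probes_removed: list[tuple[str, str]] = field(default_factory=list)
    mean_intercorrelation: float | None = None
    max_beta: float | None = None
    passed: bool = True

    def __post_init__(self) -> None:
        if self.mean_intercorrelation is not None and not -1 <= self.mean_intercorrelation <= 1:
            raise ValueError("mean inter-correlation outside [-1, 1]")


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------

def beta_from_intensities(methylated, unmethylated, offset: float = 100.0):
    """Methylation fraction from allele intensities: M / (U + M + offset).

    The +100 offset regularizes low-intensity calls; the result is always in
    [0, 1). Accepts scalars or arrays.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    out = m / (u + m + offset)
    return float(out) if out.ndim == 0 else out


def beta_to_m(beta, eps: float = EPS):
    """logit2 transform: M = log2(beta / (1 - beta)), beta clipped to
    [eps, 1 - eps] first so boundary values stay finite."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    out = np.log2(b / (1 - b))
    return float(out) if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    # logistic on base-2 scale, written to avoid overflow for large |M|
    out = np.where(m >= 0, 1.0 / (1.0 + 2.0 ** (-m)), 2.0 ** m / (1.0 + 2.0 ** m))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Sample / probe filters
# ---------------------------------------------------------------------------

def filter_samples(
    ds: MethylationDataset,
    det: DetectionInfo,
    max_fail_fraction: float = 0.10,
    p_threshold: float = 0.01,
) -> tuple[MethylationDataset, QCReport]:
    """Remove samples whose fraction of failed probe calls (detection
    p > ``p_threshold``) strictly exceeds ``max_fail_fraction``."""
    det = det.aligned_to(ds)
    fail_frac = (det.detection_p.to_numpy() > p_threshold).mean(axis=0)
    keep = fail_frac <= max_fail_fraction
    report = QCReport(
        samples_removed=[
            (sid, f"detection failure fraction {f:.3f} > {max_fail_fraction}")
            for sid, f, k in zip(ds.sample_ids, fail_frac, keep)
            if not k
        ]
    )
    if not keep.any():
        raise ValueError("all samples removed by detection-p filter")
    kept = ds.restrict_samples(ds.sample_ids[keep])
    if report.samples_removed:
        logger.info("%s: removed %d samples by detection-p filter",
                    ds.dataset_id, len(report.samples_removed))
    return kept, report


def filter_probes(
    ds: MethylationDataset,
    det: DetectionInfo | None,
    ann: ProbeAnnotation,
    drop_sex_chrom: bool = False,
    p_threshold: float = 0.01,
    min_bead_count: int = 3,
    bead_sample_fraction: float = 0.05,
) -> tuple[MethylationDataset, QCReport]:
    """Remove unreliable probes.

    A probe is dropped when it is unannotated; has any missing beta-value; has
    any detection p > ``p_threshold``; has bead count < ``min_bead_count`` in
    at least ``bead_sample_fraction`` of samples; is not a CpG probe; maps to
    multiple genomic locations; is SNP-associated; or (when ``drop_sex_chrom``)
    lies on chrX/chrY. The first applicable reason is recorded.
    """
    reasons: dict[str, str] = {}
    ann_df = ann.df

    def mark(mask: pd.Series | np.ndarray, reason: str) -> None:
        for pid in ds.probe_ids[np.asarray(mask)]:
            reasons.setdefault(pid, reason)

    mark(~ds.probe_ids.isin(ann_df.index), "unannotated")
    mark(ds.beta.isna().any(axis=1).to_numpy(), "missing beta")
    if det is not None:
        det = det.aligned_to(ds)
        mark((det.detection_p.to_numpy() > p_threshold).any(axis=1), "detection p")
        if det.bead_count is not None:
            low = (det.bead_count.to_numpy() < min_bead_count).mean(axis=1)
            mark(low >= bead_sample_fraction, "low bead count")

    sub = ann_df.reindex(ds.probe_ids)
    annotated = ds.probe_ids.isin(ann_df.index)

    def flag(col: str) -> np.ndarray:
        return sub[col].astype("boolean").fillna(False).to_numpy(dtype=bool)

    mark(~flag("is_cg") & annotated, "non-CpG")
    mark(flag("is_multimapping"), "multimapping")
    mark(flag("is_snp_associated"), "SNP-associated")
    if drop_sex_chrom:
        mark(sub["chrom"].isin(["chrX", "chrY", "X", "Y"]).to_numpy(), "sex chromosome")

    keep = [pid for pid in ds.probe_ids if pid not in reasons]
    report = QCReport(probes_removed=sorted(reasons.items()))
    if reasons:
        logger.info("%s: removed %d probes (%s)", ds.dataset_id, len(reasons),
                    pd.Series([r for _, r in reasons.items()]).value_counts().to_dict())
    return ds.restrict_probes(keep), report


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_missing(ds: MethylationDataset, k: int = 5) -> MethylationDataset:
    """k-nearest-neighbour imputation of missing beta-values.

    Neighbours are other *samples*; distance is Euclidean over the probes both
    samples have observed (NaN-aware, count-rescaled). Probes observed in
    fewer than ``k`` samples are dropped first (with a warning) so every
    missing call has at least ``k`` candidate donors.
    """
    beta = ds.beta
    n_obs = beta.notna().sum(axis=1)
    if (n_obs == 0).all():
        raise ValueError("dataset is fully missing; cannot impute")
    droppable = n_obs < k
    if droppable.any():
        logger.warning("%s: dropping %d probes with < %d observed samples before imputation",
                       ds.dataset_id, int(droppable.sum()), k)
        beta = beta.loc[~droppable]
    if not beta.isna().any().any():
        return MethylationDataset(beta.copy(), ds.platform, ds.dataset_id)
    # samples are rows for the imputer (donors are nearest samples)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(beta.to_numpy(dtype=float).T).T
    out = pd.DataFrame(np.clip(filled, 0.0, 1.0), index=beta.index, columns=beta.columns)
    return MethylationDataset(out, ds.platform, ds.dataset_id)


# ---------------------------------------------------------------------------
# Batch adjustment (empirical-Bayes location/scale, parametric priors)
# ---------------------------------------------------------------------------

class ComBat(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch correction for M-values.

    Per feature (probe), the data are standardized against the batch-size
    weighted grand mean and pooled variance; per-batch location (gamma) and
    scale (delta^2) estimates are then shrunk toward cross-feature priors
    (normal and inverse-gamma, method-of-moments hyperparameters, solved by
    the standard fixed-point iteration) and removed. The per-feature plain
    mean over samples is restored exactly after correction.

    sklearn orientation: ``X`` is (n_samples, n_features); ``batch`` is a
    length-``n_samples`` label vector passed to :meth:`fit_transform`.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, batch):
        self.fit_transform(X, batch)
        return self

    def transform(self, X, batch=None):
        if not hasattr(self, "adjusted_"):
            raise RuntimeError("ComBat must be fit first")
        return self.adjusted_

    def fit_transform(self, X, batch):
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.shape[0] != batch.shape[0]:
            raise ValueError("batch labels must match the number of samples")
        levels, inv = np.unique(batch, return_inverse=True)
        counts = np.bincount(inv)
        singletons = levels[counts < 2]
        if len(singletons) and len(levels) > 1:
            raise ValueError(f"singleton batch(es): {singletons.tolist()}")
        if len(levels) == 1:
            self.adjusted_ = X.copy()
            self.batch_levels_ = levels
            return self.adjusted_

        n, p = X.shape
        orig_mean = X.mean(axis=0)
        # batch means per feature: (n_batch, p)
        bmeans = np.stack([X[inv == i].mean(axis=0) for i in range(len(levels))])
        w = counts / n
        grand = w @ bmeans                                # (p,)
        resid = X - bmeans[inv]
        var_pooled = np.maximum((resid ** 2).mean(axis=0), 1e-12)
        sd = np.sqrt(var_pooled)
        Z = (X - grand) / sd

        gamma_hat = np.stack([Z[inv == i].mean(axis=0) for i in range(len(levels))])
        delta_hat = np.stack([
            np.maximum(Z[inv == i].var(axis=0, ddof=1), 1e-12) for i in range(len(levels))
        ])

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(len(levels)):
            g, d2 = gamma_hat[i], delta_hat[i]
            g_bar, t2 = g.mean(), g.var(ddof=1)
            m, s2 = d2.mean(), d2.var(ddof=1)
            if s2 <= 0:
                a_prior, b_prior = None, None
            else:
                a_prior = (2 * s2 + m ** 2) / s2
                b_prior = (m * s2 + m ** 3) / s2
            n_i = counts[i]
            Zi = Z[inv == i]
            g_new, d_new = g.copy(), d2.copy()
            for _ in range(self.max_iter):
                g_old, d_old = g_new, d_new
                if t2 <= 0:
                    g_new = np.full_like(g, g_bar)
                else:
                    g_new = (n_i * t2 * g + d_old * g_bar) / (n_i * t2 + d_old)
                if a_prior is None:
                    d_new = d_old
                else:
                    sse = ((Zi - g_new) ** 2).sum(axis=0)
                    d_new = (b_prior + 0.5 * sse) / (n_i / 2.0 + a_prior - 1.0)
                    d_new = np.maximum(d_new, 1e-12)
                if (np.max(np.abs(g_new - g_old)) < self.tol
                        and np.max(np.abs(d_new - d_old)) < self.tol):
                    break
            gamma_star[i] = g_new
            delta_star[i] = d_new

        Zstar = (Z - gamma_star[inv]) / np.sqrt(delta_star[inv])
        out = Zstar * sd + grand
        out += orig_mean - out.mean(axis=0)   # restore per-feature plain mean
        self.adjusted_ = out
        self.batch_levels_ = levels
        self.gamma_star_, self.delta_star_ = gamma_star, delta_star
        return out


def adjust_batch(
    m_values: pd.DataFrame,
    batch_labels: Sequence,
    position_labels: Sequence | None = None,
) -> pd.DataFrame:
    """Adjust a probes x samples M-value matrix for known batch factors.

    ``batch_labels`` (e.g. plate) is corrected first; ``position_labels``
    (e.g. position on plate), when given, in a second pass.
    """
    out = ComBat().fit_transform(m_values.to_numpy(dtype=float).T, batch_labels).T
    if position_labels is not None:
        out = ComBat().fit_transform(out.T, position_labels).T
    return pd.DataFrame(out, index=m_values.index, columns=m_values.columns)


# ---------------------------------------------------------------------------
# Cross-dataset operations
# ---------------------------------------------------------------------------

def intersect_probes(datasets: Sequence[MethylationDataset]) -> list[MethylationDataset]:
    """Restrict every dataset to the probes common to all of them, ordered as
    in the first dataset."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    common = set(datasets[0].probe_ids)
    for ds in datasets[1:]:
        common &= set(ds.probe_ids)
    if not common:
        raise ValueError("empty probe intersection across datasets")
    ordered = [pid for pid in datasets[0].probe_ids if pid in common]
    logger.info("probe intersection across %d datasets: %d probes", len(datasets), len(ordered))
    return [ds.restrict_probes(ordered) for ds in datasets]


def qc_dataset(
    ds: MethylationDataset,
    min_intercorrelation: float = 0.97,
    min_max_beta: float = 0.99,
) -> QCReport:
    """Dataset-level QC: mean pairwise Pearson correlation between samples and
    the matrix-wide maximum beta. Failure is flagged, not fatal — the check is
    an inclusion screen for externally processed data."""
    if ds.n_samples < 2:
        raise ValueError("dataset-level QC needs at least 2 samples")
    mat = ds.beta.to_numpy(dtype=float)
    corr = np.corrcoef(mat, rowvar=False)
    iu = np.triu_indices(ds.n_samples, k=1)
    mean_corr = float(np.nanmean(corr[iu]))
    max_beta = float(np.nanmax(mat))
    passed = mean_corr > min_intercorrelation and max_beta > min_max_beta
    if not passed:
        logger.warning("%s failed dataset QC: mean r=%.4f, max beta=%.4f",
                       ds.dataset_id, mean_corr, max_beta)
    return QCReport(mean_intercorrelation=mean_corr, max_beta=max_beta, passed=passed)
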