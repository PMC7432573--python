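"""Three-state beta-mixture quantile normalization.

Methylation beta-values are well described by a three-component beta mixture:
unmethylated (hypo), hemi-methylated (hemi) and methylated (hyper) states.
Mapping one distribution onto another state-by-state — quantile matching
through the fitted beta CDFs for the outer states, a linear bridge across the
hemi state to avoid boundary discontinuities — gives a monotone [0,1] -> [0,1]
transform. The same machinery serves two purposes:

* within-dataset adjustment of Infinium Type I vs Type II probe designs, and
* cross-dataset calibration of every sample to a gold-standard reference
  profile, so that cohorts measured on different platforms and in different
  labs become comparable before clock training.

The mixture is fit by EM with a deterministic quantile-based initialization;
the M-step maximizes the weighted beta log-likelihood from sufficient
statistics, so iterations are cheap and the log-likelihood never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .data import MethylationDataset

logger = logging.getLogger(__name__)

STATE_NAMES = ("hypo", "hemi", "hyper")
_CLIP = 1e-6


def _mom_beta(values: np.ndarray) -> tuple[float, float]:
    """Method-of-moments beta shape parameters, guarded for tiny variance."""
    m = float(np.mean(values))
    v = float(np.var(values))
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = max(min(v, m * (1 - m) * 0.99), 1e-6)
    common = m * (1 - m) / v - 1
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


class BetaMixtureModel(BaseEstimator):
    """Three-component beta mixture fit by EM.

    Parameters
    ----------
    max_iter : int
        EM iteration cap.
    tol : float
        Convergence threshold on the log-likelihood change.
    init_quantiles : tuple of float
        Quantile levels at which the input is cut into three groups for the
        deterministic method-of-moments initialization.

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_ : (3,) mixing proportions, summing to 1.
    shape_a_, shape_b_ : (3,) beta shape parameters, components ordered by
        increasing mean (hypo < hemi < hyper).
    loglik_ : final log-likelihood; ``loglik_trace_`` the per-iteration trace.
    n_iter_ : EM iterations used.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6,
                 init_quantiles: tuple[float, float] = (0.2, 0.75)):
        self.max_iter = max_iter
        self.tol = tol
        self.init_quantiles = init_quantiles

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _component_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """(n, 3) log density of each component at each value."""
        lx, l1x = np.log(x)[:, None], np.log1p(-x)[:, None]
        return (a - 1) * lx + (b - 1) * l1x - special.betaln(a, b)

    @staticmethod
    def _mstep_shapes(a0: float, b0: float, s1: float, s2: float, r: float
                      ) -> tuple[float, float]:
        """Maximize r-weighted beta log-likelihood given sufficient statistics
        s1 = sum(r_i log x_i), s2 = sum(r_i log(1-x_i)), r = sum(r_i)."""

        def neg(theta):
            a, b = np.exp(theta)
            return r * special.betaln(a, b) - (a - 1) * s1 - (b - 1) * s2

        def grad(theta):
            a, b = np.exp(theta)
            da = r * (special.digamma(a) - special.digamma(a + b)) - s1
            db = r * (special.digamma(b) - special.digamma(a + b)) - s2
            return np.array([da * a, db * b])

        x0 = np.log([a0, b0])
        res = optimize.minimize(neg, x0, jac=grad, method="L-BFGS-B")
        if res.fun <= neg(x0):
            a, b = np.exp(res.x)
            return float(a), float(b)
        return a0, b0  # keep previous parameters if the step did not improve

    # -- API ---------------------------------------------------------------

    def fit(self, values, y=None) -> "BetaMixtureModel":
        x = np.clip(np.asarray(values, dtype=float).ravel(), _CLIP, 1 - _CLIP)
        x = x[np.isfinite(x)]
        if x.size < 50:
            raise ValueError(f"need >= 50 values to fit a beta mixture, got {x.size}")
        if np.ptp(x) < 1e-12:
            raise ValueError("degenerate input: all values equal")

        q1, q2 = np.quantile(x, self.init_quantiles)
        groups = [x[x <= q1], x[(x > q1) & (x <= q2)], x[x > q2]]
        a = np.empty(3)
        b = np.empty(3)
        for i, g in enumerate(groups):
            a[i], b[i] = _mom_beta(g if g.size >= 2 else x)
        w = np.array([max(g.size, 1) for g in groups], dtype=float)
        w /= w.sum()

        lx, l1x = np.log(x), np.log1p(-x)
        trace: list[float] = []
        prev_ll = -np.inf
        for it in range(1, self.max_iter + 1):
            logp = self._component_logpdf(x, a, b) + np.log(w)
            norm = special.logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logp - norm[:, None])
            w = resp.mean(axis=0)
            w = np.maximum(w, 1e-12)
            w /= w.sum()
            for i in range(3):
                r = resp[:, i]
                a[i], b[i] = self._mstep_shapes(a[i], b[i],
                                                float(r @ lx), float(r @ l1x),
                                                float(r.sum()))
            if abs(ll - prev_ll) < self.tol:
                break
            prev_ll = ll

        order = np.argsort(a / (a + b))
        self.weights_ = w[order]
        self.shape_a_ = a[order]
        self.shape_b_ = b[order]
        self.loglik_trace_ = trace
        self.loglik_ = trace[-1]
        self.n_iter_ = len(trace)
        return self

    @property
    def means_(self) -> np.ndarray:
        return self.shape_a_ / (self.shape_a_ + self.shape_b_)

    def responsibilities(self, values) -> np.ndarray:
        x = np.clip(np.asarray(values, dtype=float).ravel(), _CLIP, 1 - _CLIP)
        logp = self._component_logpdf(x, self.shape_a_, self.shape_b_) + np.log(self.weights_)
        return np.exp(logp - special.logsumexp(logp, axis=1)[:, None])

    def states(self, values) -> np.ndarray:
        """Max-posterior state per value (0=hypo, 1=hemi, 2=hyper); ties break
        toward the lower-mean state."""
        return np.argmax(self.responsibilities(values), axis=1)

    def state_boundaries(self, n_grid: int = 4001) -> tuple[float, float]:
        """Beta-value thresholds (t1, t2) separating hypo/hemi and hemi/hyper
        max-posterior assignment regions."""
        grid = np.linspace(_CLIP, 1 - _CLIP, n_grid)
        s = self.states(grid)
        hypo = grid[s == 0]
        hyper = grid[s == 2]
        t1 = float(hypo.max()) if hypo.size else float(grid[0])
        t2 = float(hyper.min()) if hyper.size else float(grid[-1])
        if t2 <= t1:  # hemi state swallowed; split at the crossover
            t2 = min(t1 + 1e-6, 1 - _CLIP)
        return t1, t2

    def cdf(self, values, component: int) -> np.ndarray:
        return stats.beta.cdf(values, self.shape_a_[component], self.shape_b_[component])

    def ppf(self, q, component: int) -> np.ndarray:
        return stats.beta.ppf(q, self.shape_a_[component], self.shape_b_[component])

    def to_dict(self) -> dict:
        return {
            "weights": self.weights_.tolist(),
            "shape_a": self.shape_a_.tolist(),
            "shape_b": self.shape_b_.tolist(),
            "loglik": self.loglik_,
            "n_iter": self.n_iter_,
            "loglik_trace": self.loglik_trace_,
        }


def fit_beta_mixture(values, max_iter: int = 100, tol: float = 1e-6) -> BetaMixtureModel:
    """Fit a three-state beta mixture to a vector of beta-values."""
    return BetaMixtureModel(max_iter=max_iter, tol=tol).fit(values)


@dataclass
class CalibrationMap:
    """Monotone [0,1] -> [0,1] map sending one beta distribution onto another.

    Hypo- and hyper-state values are mapped by beta-CDF quantile matching into
    the corresponding target component; hemi-state values are carried by a
    linear bridge between the two state-boundary images, which keeps the
    overall map continuous and non-decreasing.
    """

    source_fit: BetaMixtureModel
    target_fit: BetaMixtureModel
    t1: float
    t2: float
    g1: float  # image of t1 under the hypo map
    g2: float  # image of t2 under the hyper map

    def __call__(self, values) -> np.ndarray:
        v = np.clip(np.asarray(values, dtype=float), _CLIP, 1 - _CLIP)
        scalar = v.ndim == 0
        v = np.atleast_1d(v)
        out = np.empty_like(v)

        lo = v <= self.t1
        hi = v >= self.t2
        mid = ~lo & ~hi
        if lo.any():
            q = self.source_fit.cdf(v[lo], 0)
            out[lo] = self.target_fit.ppf(q, 0)
        if hi.any():
            q = self.source_fit.cdf(v[hi], 2)
            out[hi] = self.target_fit.ppf(q, 2)
        if mid.any():
            frac = (v[mid] - self.t1) / (self.t2 - self.t1)
            out[mid] = self.g1 + frac * (self.g2 - self.g1)
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def to_dict(self) -> dict:
        return {
            "source": self.source_fit.to_dict(),
            "target": self.target_fit.to_dict(),
            "boundaries": [self.t1, self.t2],
            "boundary_images": [self.g1, self.g2],
        }


def build_calibration(
    sample_values,
    gold_values=None,
    *,
    gold_fit: BetaMixtureModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CalibrationMap:
    """Build the monotone map calibrating ``sample_values`` onto the gold
    distribution. A pre-fitted gold mixture can be supplied to avoid refits
    when calibrating many samples against one reference."""
    src = fit_beta_mixture(sample_values, max_iter=max_iter, tol=tol)
    if gold_fit is None:
        if gold_values is None:
            raise ValueError("provide gold_values or gold_fit")
        gold_fit = fit_beta_mixture(gold_values, max_iter=max_iter, tol=tol)
    t1, t2 = src.state_boundaries()
    g1 = float(gold_fit.ppf(src.cdf(t1, 0), 0))
    g2 = float(gold_fit.ppf(src.cdf(t2, 2), 2))
    if g2 <= g1:  # degenerate fits; keep the bridge monotone
        g2 = min(g1 + 1e-9, 1.0)
    return CalibrationMap(src, gold_fit, t1, t2, g1, g2)


class GoldStandardCalibrator(BaseEstimator, TransformerMixin):
    """Transformer calibrating every sample to a gold-standard mean profile.

    ``fit(X_gold)`` takes the gold dataset (n_samples, n_probes) and stores
    its per-probe mean beta profile plus the mixture fitted to that profile;
    ``transform(X)`` then maps each query sample's distribution onto the gold
    distribution via its own :class:`CalibrationMap`.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None) -> "GoldStandardCalibrator":
        X = np.asarray(X, dtype=float)
        profile = X.mean(axis=0) if X.ndim == 2 else X
        self.gold_profile_ = profile
        self.gold_fit_ = fit_beta_mixture(profile, max_iter=self.max_iter, tol=self.tol)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for i, row in enumerate(X):
            cmap = build_calibration(row, gold_fit=self.gold_fit_,
                                     max_iter=self.max_iter, tol=self.tol)
            out[i] = cmap(row)
        return out


def calibrate_dataset(
    ds: MethylationDataset,
    gold_profile: Mapping[str, float] | pd.Series,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MethylationDataset:
    """Calibrate every sample of ``ds`` to a gold-standard mean beta profile
    (probe id -> mean beta). The dataset is restricted to the probes shared
    with the profile; fewer than 50 shared probes is an error."""
    profile = pd.Series(gold_profile, dtype=float)
    shared = [pid for pid in ds.probe_ids if pid in profile.index]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} probes shared with the gold profile; need >= 50")
    sub = ds.restrict_probes(shared)
    calib = GoldStandardCalibrator(max_iter=max_iter, tol=tol)
    calib.fit(profile.loc[shared].to_numpy()[None, :])
    mapped = calib.transform(sub.beta.to_numpy(dtype=float).T).T
    out = pd.DataFrame(mapped, index=sub.probe_ids, columns=sub.sample_ids)
    return MethylationDataset(out, ds.platform, ds.dataset_id)
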