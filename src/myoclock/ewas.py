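"""Age-EWAS: moderated-variance linear models, DMR calling, enrichment and
overlap tests.

Per CpG, methylation is regressed on age with sex and dataset id as
covariates. Paired designs (repeated biopsies of one subject, twins) are
handled by estimating a single consensus within-subject correlation and
fitting generalized least squares with an exchangeable within-block
correlation structure. Residual variances are then moderated by empirical
Bayes: a scaled inverse-chi-square prior (d0, s0^2) is fitted across probes
by method of moments on log variances (digamma/trigamma inversion), each
probe's variance is shrunk toward s0^2, and the resulting t-statistics gain
d0 extra degrees of freedom — this is what makes small-sample per-probe
inference stable at array scale.

Downstream: BH false discovery rates (threshold 0.005 throughout);
differentially methylated regions as clusters of >= 2 nearby (<= 1 kb gap),
direction-consistent significant probes; Fisher-exact enrichment of probe
panels in CpG-island context and chromatin states; a Monte-Carlo overlap
null for comparing probe panels; and a probe-count-bias-aware gene-set test
using the Wallenius noncentral hypergeometric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import CHROMATIN_STATES, DMR, ISLAND_CONTEXTS, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

FDR_SIGNIFICANT = 0.005


# ---------------------------------------------------------------------------
# Variance moderation
# ---------------------------------------------------------------------------

@dataclass
class ModeratedVariancePrior:
    """Scaled inverse-chi-square prior on residual variances: d0 prior degrees
    of freedom (possibly +inf) and s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone decreasing
    trigamma, with asymptotic starting values)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if -step / x < 1e-10:
            break
    return float(x)


def estimate_prior(s_sq, d: float) -> ModeratedVariancePrior:
    """Fit (d0, s0^2) across probes by matching the mean and variance of
    log s^2 against the scaled inverse-chi-square model.

    If the observed spread of log variances does not exceed what d residual
    degrees of freedom alone would produce, d0 = +inf (all probes share one
    variance).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.size < 100:
        raise ValueError("need >= 100 probes to estimate the variance prior")
    if (s_sq <= 0).any():
        raise ValueError("residual variances must be positive")
    z = np.log(s_sq)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return ModeratedVariancePrior(np.inf, float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedVariancePrior(d0, s0_sq)


def moderate_variances(s_sq, d: float, prior: ModeratedVariancePrior) -> np.ndarray:
    """Posterior (shrunken) variances: (d0 s0^2 + d s^2) / (d0 + d)."""
    s_sq = np.asarray(s_sq, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    if prior.d0 == 0:
        return s_sq.copy()
    return (prior.d0 * prior.s0_sq + d * s_sq) / (prior.d0 + d)


# ---------------------------------------------------------------------------
# Design matrix and GLS whitening
# ---------------------------------------------------------------------------

def _build_design(sheet: SampleSheet, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(sheet.df))}
    for cov in covariates:
        if cov == "age":
            cols["age"] = sheet.df["age"].to_numpy(dtype=float)
        elif cov in ("sex", "dataset_id", "condition"):
            values = sheet.df[cov].astype(str)
            levels = pd.unique(values)
            for lev in levels[1:]:  # first level is the reference
                cols[f"{cov}[{lev}]"] = (values == lev).to_numpy(dtype=float)
        else:
            cols[cov] = pd.to_numeric(sheet.df[cov]).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=sheet.df["sample_id"])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X


def _blocks_from(sheet: SampleSheet, block: str) -> list[np.ndarray]:
    labels = sheet.df[block]
    blocks = []
    for lab, sub in sheet.df.groupby(labels.fillna("__none__"), sort=False):
        idx = sub.index.to_numpy()
        if lab == "__none__":
            blocks.extend([np.array([i]) for i in idx])
        else:
            blocks.append(idx)
    return blocks


def estimate_consensus_correlation(
    Y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray], max_probes: int = 500
) -> float:
    """Consensus intra-block correlation: per-probe residual within-block
    correlations (moment estimates), averaged on the atanh scale."""
    multi = [b for b in blocks if len(b) >= 2]
    if not multi:
        return 0.0
    pick = np.linspace(0, Y.shape[0] - 1, min(max_probes, Y.shape[0])).astype(int)
    H = X @ np.linalg.pinv(X)
    E = Y[pick] - Y[pick] @ H.T
    d = X.shape[0] - X.shape[1]
    s2 = (E ** 2).sum(axis=1) / max(d, 1)
    rhos = []
    n_pairs = sum(len(b) * (len(b) - 1) // 2 for b in multi)
    for g in range(E.shape[0]):
        if s2[g] <= 0:
            continue
        cross = 0.0
        for b in multi:
            e = E[g, b]
            cross += (e.sum() ** 2 - (e ** 2).sum()) / 2.0
        rhos.append(np.clip(cross / (n_pairs * s2[g]), -0.95, 0.95))
    if not rhos:
        return 0.0
    rho = float(np.tanh(np.mean(np.arctanh(rhos))))
    max_m = max(len(b) for b in multi)
    # keep the exchangeable correlation matrix positive definite
    return float(np.clip(rho, -1.0 / (max_m - 1) + 1e-3, 0.99))


def _whiten(M: np.ndarray, blocks: list[np.ndarray], rho: float, axis: int) -> np.ndarray:
    """Apply V^{-1/2} for exchangeable correlation rho within each block,
    along ``axis`` (0: rows are samples; 1: columns are samples)."""
    out = M.astype(float).copy()
    for b in blocks:
        m = len(b)
        if m == 1:
            continue
        if axis == 0:
            sub = out[b, :]
            mean = sub.mean(axis=0, keepdims=True)
            out[b, :] = (sub - mean) / np.sqrt(1 - rho) + mean / np.sqrt(1 + (m - 1) * rho)
        else:
            sub = out[:, b]
            mean = sub.mean(axis=1, keepdims=True)
            out[:, b] = (sub - mean) / np.sqrt(1 - rho) + mean / np.sqrt(1 + (m - 1) * rho)
    return out


# ---------------------------------------------------------------------------
# EWAS fit
# ---------------------------------------------------------------------------

def ewas_fit(
    values: pd.DataFrame,
    sheet: SampleSheet,
    covariates: Sequence[str] = ("age", "sex", "dataset_id"),
    block: str | None = "subject_id",
    coef: str = "age",
    prior: ModeratedVariancePrior | None = None,
) -> pd.DataFrame:
    """Per-probe moderated regression of methylation on age and covariates.

    Parameters
    ----------
    values : DataFrame
        Probes x samples methylation matrix (beta or M scale; the slope is
        reported on whatever scale is supplied).
    sheet : SampleSheet
        Covariate source; rows are aligned to the matrix columns.
    block : str or None
        Sample-sheet column defining paired/repeated blocks (consensus
        exchangeable-correlation GLS); None for plain OLS.
    prior : ModeratedVariancePrior, optional
        Override the empirically estimated variance prior (d0=0 gives
        ordinary unmoderated t-statistics).

    Returns
    -------
    DataFrame indexed by probe id with columns ``slope`` (per year of age),
    ``se``, ``t_ordinary``, ``t_moderated``, ``p``, ``fdr``, ``direction``.
    """
    sheet = sheet.aligned_to(values.columns)
    X_df = _build_design(sheet, covariates)
    X = X_df.to_numpy()
    Y = values.to_numpy(dtype=float)
    n, p_cols = X.shape
    d = n - p_cols
    if d <= 0:
        raise ValueError("no residual degrees of freedom")
    if coef not in X_df.columns:
        raise ValueError(f"coefficient {coef!r} not in design ({list(X_df.columns)})")
    j = X_df.columns.get_loc(coef)

    rho = 0.0
    if block is not None and sheet.df[block].notna().any():
        blocks = _blocks_from(sheet, block)
        rho = estimate_consensus_correlation(Y, X, blocks)
        if abs(rho) > 1e-8:
            X = _whiten(X, blocks, rho, axis=0)
            Y = _whiten(Y, blocks, rho, axis=1)
        logger.info("consensus intra-block correlation: %.3f", rho)

    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T                     # (p, n)
    B = Y @ pinv.T                           # (probes, p)
    resid = Y - B @ X.T
    s_sq = (resid ** 2).sum(axis=1) / d
    v_j = XtX_inv[j, j]
    slope = B[:, j]
    se = np.sqrt(np.maximum(s_sq, 1e-300) * v_j)
    t_ord = slope / se

    if prior is None:
        if len(s_sq) >= 100:
            prior = estimate_prior(np.maximum(s_sq, 1e-300), d)
        else:
            logger.warning("too few probes to estimate a variance prior; "
                           "reporting unmoderated statistics")
            prior = ModeratedVariancePrior(0.0, 1.0)
    s_tilde_sq = moderate_variances(np.maximum(s_sq, 1e-300), d, prior)
    t_mod = slope / np.sqrt(s_tilde_sq * v_j)
    df_total = d if prior.d0 == 0 else prior.d0 + d
    p_val = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    out = pd.DataFrame({
        "slope": slope,
        "se": se,
        "t_ordinary": t_ord,
        "t_moderated": t_mod,
        "p": p_val,
        "fdr": fdr_bh(p_val),
        "direction": np.where(slope > 0, "hyper", "hypo"),
    }, index=values.index)
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s0_sq"] = prior.s0_sq
    out.attrs["consensus_rho"] = rho
    out.attrs["residual_df"] = d
    return out


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(
    ewas: pd.DataFrame,
    ann: ProbeAnnotation,
    max_gap: int = 1000,
    fdr_cut: float = FDR_SIGNIFICANT,
) -> list[DMR]:
    """Cluster significant probes into direction-consistent regions.

    Significant probes (fdr < ``fdr_cut``) are sorted by genomic position;
    consecutive probes are merged while the gap is <= ``max_gap`` bp *and*
    the methylation change with age has the same sign. Clusters of >= 2
    probes are emitted.
    """
    sig = ewas[ewas["fdr"] < fdr_cut]
    if sig.empty:
        return []
    missing = sig.index.difference(ann.df.index)
    if len(missing):
        raise ValueError(f"significant probes lack annotation: {list(missing[:5])}")
    tab = sig.join(ann.df[["chrom", "pos"]]).sort_values(["chrom", "pos"])

    dmrs: list[DMR] = []
    cluster: list[tuple[str, int, str, float, float]] = []  # pid,pos,dir,fdr,slope

    def flush() -> None:
        if len(cluster) >= 2:
            dmrs.append(DMR(
                chrom=cur_chrom,
                start=cluster[0][1],
                end=cluster[-1][1],
                probe_ids=[c[0] for c in cluster],
                direction=cluster[0][2],
                min_fdr=min(c[3] for c in cluster),
                mean_slope=float(np.mean([c[4] for c in cluster])),
            ))

    cur_chrom = None
    for pid, row in tab.iterrows():
        rec = (pid, int(row["pos"]), row["direction"], float(row["fdr"]), float(row["slope"]))
        if cluster and row["chrom"] == cur_chrom \
                and rec[1] - cluster[-1][1] <= max_gap and rec[2] == cluster[-1][2]:
            cluster.append(rec)
        else:
            if cluster:
                flush()
            cluster = [rec]
            cur_chrom = row["chrom"]
    if cluster:
        flush()
    return dmrs


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------

def enrichment_fisher(
    foreground: Sequence[str],
    background: Sequence[str],
    ann: ProbeAnnotation,
    category: str = "island_context",
) -> pd.DataFrame:
    """Fisher-exact enrichment of a probe panel across annotation levels.

    For each level of ``category`` (4 island contexts or 15 chromatin
    states), the 2x2 table is (in/out of level) x (in/out of foreground)
    over the background universe; BH correction is applied across the
    category's levels.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground probe set")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    levels = {"island_context": ISLAND_CONTEXTS, "chromatin_state": CHROMATIN_STATES}[category]
    lab = ann.df.loc[list(bg), category]
    in_fg = lab.index.isin(fg)

    rows = []
    for lev in levels:
        in_lev = (lab == lev).to_numpy()
        a = int((in_lev & in_fg).sum())
        b = int((~in_lev & in_fg).sum())
        c = int((in_lev & ~in_fg).sum())
        dd = int((~in_lev & ~in_fg).sum())
        _, p = stats.fisher_exact([[a, b], [c, dd]], alternative="two-sided")
        odds = (a * dd) / (b * c) if b * c > 0 else np.inf if a * dd > 0 else np.nan
        rows.append({"level": lev, "n_foreground": a, "n_background": a + c,
                     "odds_ratio": odds, "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = fdr_bh(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo overlap null
# ---------------------------------------------------------------------------

try:
    from numba import njit

    @njit(cache=False)
    def _overlap_draws(n_bg: int, draw_size: int, is_member, n_draws: int, seed: int):
        """Floyd partial sampling of `draw_size` indices without replacement
        from range(n_bg), counting members of the marked panel per draw."""
        np.random.seed(seed)
        out = np.empty(n_draws, dtype=np.int64)
        flags = np.zeros(n_bg, dtype=np.bool_)
        chosen = np.empty(draw_size, dtype=np.int64)
        for dr in range(n_draws):
            cnt = 0
            for jj in range(draw_size):
                j = n_bg - draw_size + jj
                t = np.random.randint(0, j + 1)
                v = j if flags[t] else t
                flags[v] = True
                chosen[jj] = v
                if is_member[v]:
                    cnt += 1
            out[dr] = cnt
            for jj in range(draw_size):
                flags[chosen[jj]] = False
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False


def _overlap_draws_py(n_bg, draw_size, is_member, n_draws, seed):  # pragma: no cover
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws, dtype=np.int64)
    for dr in range(n_draws):
        draw = rng.choice(n_bg, size=draw_size, replace=False)
        out[dr] = int(is_member[draw].sum())
    return out


@dataclass
class OverlapTestResult:
    observed_overlap: int
    max_null_overlap: int
    p_value: float
    null_mean: float
    null_var: float
    n_draws: int


def random_overlap_test(
    panel_a: Sequence[str],
    panel_b: Sequence[str],
    background: Sequence[str],
    draw_size: int | None = None,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Monte-Carlo null for the overlap between two probe panels.

    Draws ``n_draws`` uniform subsets of size ``draw_size`` (default:
    |panel_a ∩ background|) from the background without replacement and
    records their overlap with panel_b ∩ background. The tail probability is
    the add-one Monte-Carlo estimate of P(overlap >= observed).
    """
    bg = pd.Index(pd.unique(np.asarray(list(background), dtype=object)))
    a_in = set(panel_a) & set(bg)
    b_in = set(panel_b) & set(bg)
    if draw_size is None:
        draw_size = len(a_in)
    if draw_size > len(bg):
        raise ValueError("draw_size exceeds the background size")
    observed = len(a_in & b_in)
    is_member = bg.isin(b_in)
    sampler = _overlap_draws if _HAVE_NUMBA else _overlap_draws_py
    counts = np.asarray(sampler(len(bg), draw_size, is_member, int(n_draws),
                                int(seed) % (2 ** 31)))
    p = (1.0 + float((counts >= observed).sum())) / (1.0 + n_draws)
    return OverlapTestResult(
        observed_overlap=observed,
        max_null_overlap=int(counts.max()),
        p_value=p,
        null_mean=float(counts.mean()),
        null_var=float(counts.var(ddof=1)),
        n_draws=int(n_draws),
    )


# ---------------------------------------------------------------------------
# Bias-aware gene-set test
# ---------------------------------------------------------------------------

def gene_set_test(
    significant_probes: Sequence[str],
    background_probes: Sequence[str],
    ann: ProbeAnnotation,
    gene_sets: Mapping[str, Sequence[str]],
    bias_correction: bool = True,
) -> pd.DataFrame:
    """Gene-set over-representation test correcting for probe-count bias.

    Genes with many probes are more likely to contain a significant probe by
    chance alone. A gene is scored significant when >= 1 of its probes is
    significant; per set, the tail probability of the significant-gene count
    comes from a Wallenius noncentral hypergeometric distribution whose odds
    parameter is the ratio of mean probe counts inside vs outside the set
    (``bias_correction=False`` gives the naive central hypergeometric test).
    """
    bg = set(background_probes)
    sig = set(significant_probes) & bg
    sub = ann.df.loc[ann.df.index.isin(bg)]
    gene_probes: dict[str, int] = {}
    gene_sig: dict[str, bool] = {}
    for pid, genes in sub["genes"].items():
        for g in genes:
            gene_probes[g] = gene_probes.get(g, 0) + 1
            gene_sig[g] = gene_sig.get(g, False) or (pid in sig)
    if not gene_probes:
        raise ValueError("no annotated genes in the background")
    universe = sorted(gene_probes)
    counts = np.array([gene_probes[g] for g in universe], dtype=float)
    is_sig = np.array([gene_sig[g] for g in universe])
    M, n_sig = len(universe), int(is_sig.sum())

    rows = []
    for name, genes in gene_sets.items():
        in_set = np.isin(universe, list(genes))
        K = int(in_set.sum())
        if K == 0:
            raise ValueError(f"gene set {name!r} is empty after intersection "
                             "with the annotated universe")
        k = int((in_set & is_sig).sum())
        if bias_correction and K < M:
            odds = counts[in_set].mean() / counts[~in_set].mean()
        else:
            odds = 1.0
        if abs(odds - 1.0) < 1e-12 or K == M:
            p = float(stats.hypergeom.sf(k - 1, M, K, n_sig))
        else:
            p = float(stats.nchypergeom_wallenius.sf(k - 1, M, K, n_sig, odds))
        rows.append({"gene_set": name, "n_genes": K, "n_significant": k,
                     "odds": odds, "p": min(max(p, 0.0), 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = fdr_bh(out["p"].to_numpy())
    return out
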