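"""Synthetic multi-dataset methylation generator.

Emulates the statistical structure of a multi-cohort skeletal-muscle
methylation compendium: 12 datasets on three array generations whose probe
sets intersect to a common core, heterogeneous per-dataset age ranges whose
pooled distribution is bimodal (middle ages under-represented), paired
designs (twins, pre/post interventions) sharing latent subject effects,
per-dataset batch shifts, and a subset of age-responsive CpGs.

Effects are linear on the M (logit) scale, the standard working scale for
array methylation; per-CpG age slopes are also reported on the beta scale
via the delta method at each probe's baseline so EWAS-style effect sizes
(fraction methylation per year) are available as ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    CHROMATIN_STATES,
    ISLAND_CONTEXTS,
    MethylationDataset,
    ProbeAnnotation,
    SampleSheet,
)
from .preprocess import beta_to_m, m_to_beta

logger = logging.getLogger(__name__)

#: age strata bounds (years) for the bimodal pooled distribution
AGE_STRATA = ((18, 30), (30, 50), (50, 70), (70, 90))


@dataclass
class DatasetSpec:
    """Sampling recipe for one synthetic cohort."""

    dataset_id: str
    platform: str                      # HM27 | HM450 | HMEPIC
    strata_counts: tuple[int, int, int, int]
    constant_age: float | None = None  # all samples this age (age-invariant cohorts)
    paired: bool = False               # consecutive samples share a subject
    include_female: bool = False

    @property
    def n_samples(self) -> int:
        return int(sum(self.strata_counts))


def _paper_like_specs() -> list[DatasetSpec]:
    """12 cohorts whose strata sum to (242, 105, 275, 60) = 682 samples:
    one broad-range gold standard, one large mid/old cohort, two
    age-invariant young cohorts, one tiny cohort, and assorted young/old
    paired designs across the three platforms."""
    return [
        DatasetSpec("SYN_GOLD",  "HM450",  (24, 0, 0, 24)),
        DatasetSpec("SYN_BIG",   "HM450",  (0, 60, 222, 0), paired=True, include_female=True),
        DatasetSpec("SYN_YNG1",  "HMEPIC", (70, 0, 0, 0), paired=True),
        DatasetSpec("SYN_CONST1", "HM27",  (24, 0, 0, 0), constant_age=24.0, paired=True),
        DatasetSpec("SYN_CONST2", "HM450", (20, 0, 0, 0), constant_age=25.0, paired=True),
        DatasetSpec("SYN_TWIN",  "HM27",   (0, 0, 24, 20), paired=True),
        DatasetSpec("SYN_MID",   "HM450",  (0, 25, 25, 0), include_female=True),
        DatasetSpec("SYN_TINY",  "HM450",  (0, 0, 3, 0)),
        DatasetSpec("SYN_YNG2",  "HMEPIC", (60, 0, 0, 0), paired=True),
        DatasetSpec("SYN_YNG3",  "HM450",  (44, 0, 0, 0), paired=True),
        DatasetSpec("SYN_MIX",   "HM450",  (0, 20, 1, 0), include_female=True),
        DatasetSpec("SYN_OLD",   "HM27",   (0, 0, 0, 16), paired=True),
    ]


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic generator."""

    datasets: list[DatasetSpec] = field(default_factory=_paper_like_specs)
    common_core_size: int = 19401
    platform_extra: int = 500          # platform-specific probes beyond the core
    n_age_probes: int = 1000
    slope_sd_beta: float = 0.0015      # age slope scale, beta fraction per year
    slope_min_beta: float = 0.0005     # truncation: discard near-null slopes
    slope_max_beta: float = 0.003
    baseline_weights: tuple[float, float, float] = (0.45, 0.10, 0.45)
    baseline_shapes: tuple[tuple[float, float], ...] = ((2, 18), (5, 5), (18, 2))
    noise_sd_m: float = 3.0            # i.i.d. noise on the M scale
    batch_shift_sd_m: float = 0.5      # per-dataset global location shift (M scale)
    batch_scale_sd: float = 0.10       # per-dataset global scale distortion (log M)
    batch_probe_sd_m: float = 0.10     # residual per-probe batch component (M scale)
    pair_sd_m: float = 0.25            # latent subject effect shared within pairs
    age_reference: float = 45.0        # age at which baselines are anchored
    seed: int = 0

    @property
    def n_probes_total(self) -> int:
        return self.common_core_size + 3 * self.platform_extra

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_samples_total(self) -> int:
        return sum(d.n_samples for d in self.datasets)

    def __post_init__(self) -> None:
        if self.n_age_probes > self.common_core_size:
            raise ValueError("n_age_probes cannot exceed common_core_size")
        if self.platform_extra < 0 or self.common_core_size < 1:
            raise ValueError("infeasible probe configuration")
        for sd in (self.noise_sd_m, self.batch_shift_sd_m, self.batch_scale_sd,
                   self.batch_probe_sd_m, self.pair_sd_m, self.slope_sd_beta):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth needed to score downstream inference."""

    age_probe_ids: list[str]
    slopes_beta: pd.Series        # beta fraction / year, indexed by age probe
    slopes_m: pd.Series           # M units / year
    batch_shifts: dict[str, pd.Series]
    sample_ages: pd.Series        # indexed by sample id
    pair_assignments: pd.Series   # subject id per sample (NaN if unpaired)
    baseline_beta: pd.Series      # per-probe baseline at the reference age


def default_paper_like_config(
    scale: float = 1.0,
    common_core_size: int = 19401,
    n_age_probes: int = 1000,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """The standard 12-cohort scenario: 682 samples at scale 1 with age
    strata (242, 105, 275, 60). ``scale`` multiplies every stratum count
    (rounded half-up), preserving proportions for fast tests."""
    specs = []
    for spec in _paper_like_specs():
        counts = tuple(int(np.floor(c * scale + 0.5)) for c in spec.strata_counts)
        if sum(counts) == 0:
            counts = tuple(1 if c > 0 else 0 for c in spec.strata_counts)
        specs.append(replace(spec, strata_counts=counts))
    return SimulationConfig(datasets=specs, common_core_size=common_core_size,
                            n_age_probes=n_age_probes, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_ages(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.constant_age is not None:
        return np.full(spec.n_samples, float(spec.constant_age))
    ages = []
    for (lo, hi), count in zip(AGE_STRATA, spec.strata_counts):
        ages.append(rng.integers(lo, hi, size=count).astype(float))
    out = np.concatenate(ages)
    rng.shuffle(out)
    return out


def _truncated_slopes(n: int, cfg: SimulationConfig, rng: np.random.Generator
                      ) -> np.ndarray:
    """|slope| from a truncated half-normal on [slope_min, slope_max], with
    random sign (hypo/hyper with age both occur)."""
    mags = np.empty(0)
    while mags.size < n:
        cand = np.abs(rng.normal(0.0, cfg.slope_sd_beta, size=4 * n))
        cand = cand[(cand >= cfg.slope_min_beta) & (cand <= cfg.slope_max_beta)]
        mags = np.concatenate([mags, cand])
    return mags[:n] * rng.choice([-1.0, 1.0], size=n)


def _make_annotation(probe_ids: list[str], cfg: SimulationConfig,
                     rng: np.random.Generator) -> ProbeAnnotation:
    n = len(probe_ids)
    chrom = np.where(np.arange(n) < n // 2, "chr1s", "chr2s")
    pos = np.empty(n, dtype=int)
    for c in ("chr1s", "chr2s"):
        idx = np.flatnonzero(chrom == c)
        gaps = np.exp(rng.normal(np.log(700.0), 1.0, size=len(idx))).astype(int) + 2
        pos[idx] = 1000 + np.cumsum(gaps)
    # long-tailed gene sizes so probe-count bias is a real feature of the data
    n_genes = max(60, n // 12)
    gene_names = [f"G{i:05d}" for i in range(n_genes)]
    gene_w = rng.pareto(1.3, size=n_genes) + 1.0
    gene_w /= gene_w.sum()
    primary = rng.choice(n_genes, size=n, p=gene_w)
    genes: list[list[str]] = []
    for i in range(n):
        g = [gene_names[primary[i]]]
        u = rng.random()
        if u < 0.10:
            g.append(gene_names[rng.integers(n_genes)])
        elif u > 0.90:
            g = []
        genes.append(sorted(set(g)))
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "design_type": rng.choice(["I", "II"], size=n, p=[0.15, 0.85]),
        "island_context": rng.choice(ISLAND_CONTEXTS, size=n, p=[0.30, 0.25, 0.10, 0.35]),
        "chromatin_state": rng.choice(
            CHROMATIN_STATES, size=n,
            p=np.array([6, 5, 2, 8, 10, 3, 7, 2, 6, 2, 2, 2, 6, 9, 30]) / 100.0),
        "genes": genes,
        "is_cg": True,
        "is_snp_associated": False,
        "is_multimapping": False,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeAnnotation(df)


def simulate_multidataset(cfg: SimulationConfig | None = None
                          ) -> tuple[list[MethylationDataset], list[SampleSheet],
                                     ProbeAnnotation, SimulationTruth]:
    """Generate the full synthetic compendium.

    Returns the per-cohort beta matrices (each restricted to its platform's
    probe set), aligned sample sheets, the probe annotation, and the ground
    truth (age probes and slopes, batch shifts, ages, pair structure).
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_probes = cfg.n_probes_total
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]

    # platform probe sets: shared core + disjoint platform-specific extras
    core = probe_ids[: cfg.common_core_size]
    extras = {
        "HM27": probe_ids[cfg.common_core_size: cfg.common_core_size + cfg.platform_extra],
        "HM450": probe_ids[cfg.common_core_size + cfg.platform_extra:
                           cfg.common_core_size + 2 * cfg.platform_extra],
        "HMEPIC": probe_ids[cfg.common_core_size + 2 * cfg.platform_extra:],
    }

    comp = rng.choice(3, size=n_probes, p=np.asarray(cfg.baseline_weights))
    shapes = np.asarray(cfg.baseline_shapes, dtype=float)
    baseline_beta = np.clip(rng.beta(shapes[comp, 0], shapes[comp, 1]), 0.02, 0.98)
    baseline_m = beta_to_m(baseline_beta)

    age_idx = rng.choice(cfg.common_core_size, size=cfg.n_age_probes, replace=False)
    age_probe_ids = [core[i] for i in age_idx]
    slopes_beta = _truncated_slopes(cfg.n_age_probes, cfg, rng)
    # delta method at the probe baseline: dM/dbeta = 1 / (ln2 * b * (1-b))
    deriv = 1.0 / (np.log(2) * baseline_beta[age_idx] * (1 - baseline_beta[age_idx]))
    slopes_m_vec = slopes_beta * deriv
    slope_m = np.zeros(n_probes)
    slope_m[age_idx] = slopes_m_vec

    annotation = _make_annotation(probe_ids, cfg, rng)

    datasets: list[MethylationDataset] = []
    sheets: list[SampleSheet] = []
    batch_shifts: dict[str, pd.Series] = {}
    all_ages: dict[str, float] = {}
    pairs: dict[str, object] = {}

    for spec in cfg.datasets:
        n = spec.n_samples
        ages = _draw_ages(spec, rng)
        if spec.paired:
            ages.sort()  # pair adjacent ages (twins / repeated measures)
        # batch effect: global location + scale distortion of the whole M
        # distribution (what gold-standard calibration can undo) plus a
        # smaller independent per-probe component
        g_shift = rng.normal(0.0, cfg.batch_shift_sd_m) if cfg.batch_shift_sd_m > 0 else 0.0
        g_scale = float(np.exp(rng.normal(0.0, cfg.batch_scale_sd))) \
            if cfg.batch_scale_sd > 0 else 1.0
        probe_shift = rng.normal(0.0, cfg.batch_probe_sd_m, size=n_probes) \
            if cfg.batch_probe_sd_m > 0 else np.zeros(n_probes)
        shift = (g_scale - 1.0) * baseline_m + g_shift + probe_shift
        batch_shifts[spec.dataset_id] = pd.Series(shift, index=probe_ids)

        sample_ids = [f"{spec.dataset_id}_s{i:03d}" for i in range(n)]
        subject = np.array([pd.NA] * n, dtype=object)
        condition = np.array(["baseline"] * n, dtype=object)
        subj_effect = np.zeros((n_probes, n))
        if spec.paired and n >= 2:
            for p in range(n // 2):
                i, j = 2 * p, 2 * p + 1
                sid = f"{spec.dataset_id}_subj{p:03d}"
                subject[i] = subject[j] = sid
                condition[j] = "intervention"
                if cfg.pair_sd_m > 0:
                    u = rng.normal(0.0, cfg.pair_sd_m, size=n_probes)
                    subj_effect[:, i] = u
                    subj_effect[:, j] = u

        M = (baseline_m[:, None]
             + slope_m[:, None] * (ages[None, :] - cfg.age_reference)
             + shift[:, None]
             + subj_effect
             + (rng.normal(0.0, cfg.noise_sd_m, size=(n_probes, n))
                if cfg.noise_sd_m > 0 else 0.0))
        beta = m_to_beta(M)

        plat_probes = core + extras[spec.platform]
        frame = pd.DataFrame(beta, index=probe_ids, columns=sample_ids).loc[plat_probes]
        datasets.append(MethylationDataset(frame, spec.platform, spec.dataset_id))

        sex = np.array(["M"] * n, dtype=object)
        if spec.include_female:
            sex[rng.random(n) < 0.4] = "F"
        sheets.append(SampleSheet(pd.DataFrame({
            "sample_id": sample_ids,
            "age": ages,
            "sex": sex,
            "dataset_id": spec.dataset_id,
            "subject_id": subject,
            "condition": condition,
        })))
        all_ages.update(dict(zip(sample_ids, ages)))
        pairs.update(dict(zip(sample_ids, subject)))
        logger.info("simulated %s: n=%d, platform %s, ages %.0f-%.0f",
                    spec.dataset_id, n, spec.platform, ages.min(), ages.max())

    truth = SimulationTruth(
        age_probe_ids=age_probe_ids,
        slopes_beta=pd.Series(slopes_beta, index=age_probe_ids),
        slopes_m=pd.Series(slopes_m_vec, index=age_probe_ids),
        batch_shifts=batch_shifts,
        sample_ages=pd.Series(all_ages),
        pair_assignments=pd.Series(pairs, dtype=object),
        baseline_beta=pd.Series(baseline_beta, index=probe_ids),
    )
    return datasets, sheets, annotation, truth
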