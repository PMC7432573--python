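"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from myoclock.data import (
    CHROMATIN_STATES,
    ISLAND_CONTEXTS,
    MethylationDataset,
    ProbeAnnotation,
    SampleSheet,
)


def make_annotation(
    probe_ids,
    chrom="chr1s",
    positions=None,
    seed=0,
    **overrides,
) -> ProbeAnnotation:
    """Hand-rollable annotation for unit tests; column-level overrides allowed."""
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    if positions is None:
        positions = 1000 + 500 * np.arange(n)
    df = pd.DataFrame(
        {
            "chrom": chrom if np.isscalar(chrom) else list(chrom),
            "pos": np.asarray(positions, dtype=int),
            "design_type": rng.choice(["I", "II"], size=n),
            "island_context": rng.choice(ISLAND_CONTEXTS, size=n),
            "chromatin_state": rng.choice(CHROMATIN_STATES, size=n),
            "genes": [[f"GENE{i % 7}"] for i in range(n)],
            "is_cg": True,
            "is_snp_associated": False,
            "is_multimapping": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for col, values in overrides.items():
        df[col] = values
    return ProbeAnnotation(df)


def make_dataset(beta: np.ndarray, dataset_id="ds1", platform="SYNTH",
                 probe_prefix="cg", sample_prefix="s") -> MethylationDataset:
    n_probes, n_samples = beta.shape
    frame = pd.DataFrame(
        beta,
        index=[f"{probe_prefix}{i:05d}" for i in range(n_probes)],
        columns=[f"{sample_prefix}{j:03d}" for j in range(n_samples)],
    )
    return MethylationDataset(frame, platform=platform, dataset_id=dataset_id)


def make_sheet(sample_ids, ages, dataset_id="ds1", sex=None, subject=None) -> SampleSheet:
    n = len(sample_ids)
    return SampleSheet(pd.DataFrame({
        "sample_id": list(sample_ids),
        "age": ages,
        "sex": sex if sex is not None else ["M"] * n,
        "dataset_id": dataset_id,
        "subject_id": subject if subject is not None else [pd.NA] * n,
        "condition": "baseline",
    }))


@pytest.fixture(scope="session")
def small_sim():
    """A small 12-cohort simulation shared by read-only tests."""
    from myoclock.simulate import default_paper_like_config, simulate_multidataset

    cfg = default_paper_like_config(scale=0.1, common_core_size=600,
                                    n_age_probes=60, seed=7)
    return simulate_multidataset(cfg)
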