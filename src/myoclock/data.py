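"""Core data containers and text-format I/O.

The package works on Illumina-style methylation array data: a probes x samples
matrix of beta-values (methylation fractions in [0, 1]), an aligned sample
sheet carrying age/sex/dataset/subject metadata, and a probe annotation table
with genomic position, design type, CpG-island context, chromatin state and
gene assignments. All on-disk formats are delimited text or JSON so that every
artifact is human-inspectable and diffable.

Conventions
-----------
* Matrices are oriented probes x samples (rows are CpG probes).
* Genomic coordinates are 1-based inclusive internally; BED export converts
  to 0-based half-open.
* Missing beta-values are NaN in memory and empty cells on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("HM27", "HM450", "HMEPIC", "SYNTH")
SEXES = ("F", "M", "unknown")
ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")
#: 15-state Roadmap-style chromHMM segmentation labels.
CHROMATIN_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

MODEL_FORMAT_VERSION = 1


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class MethylationDataset:
    """A probes x samples beta-value matrix with platform tag and dataset id.

    Parameters
    ----------
    beta : DataFrame
        Rows indexed by probe id, columns by sample id; values are methylation
        fractions in [0, 1], NaN for missing.
    platform : str
        One of ``HM27``, ``HM450``, ``HMEPIC``, ``SYNTH``.
    dataset_id : str
        Cohort / GEO-style label for the dataset.
    """

    beta: pd.DataFrame
    platform: str
    dataset_id: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        _check_unique(list(self.beta.index), "probe ids")
        _check_unique(list(self.beta.columns), "sample ids")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta out of range: probe {self.beta.index[i]!r}, sample "
                f"{self.beta.columns[j]!r} has value {vals[i, j]!r} outside [0, 1]"
            )
        # normalise dtype so downstream numeric code never sees object columns
        if not all(self.beta.dtypes == float):
            self.beta = self.beta.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def n_missing(self) -> int:
        return int(self.beta.isna().to_numpy().sum())

    def restrict_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        """Return a copy restricted to ``probe_ids`` (given order kept)."""
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.beta.index)
        if len(missing):
            raise KeyError(f"{len(missing)} probes absent from dataset {self.dataset_id}")
        return MethylationDataset(self.beta.loc[idx].copy(), self.platform, self.dataset_id)

    def restrict_samples(self, sample_ids: Iterable[str]) -> "MethylationDataset":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.beta.columns)
        if len(missing):
            raise KeyError(f"{len(missing)} samples absent from dataset {self.dataset_id}")
        return MethylationDataset(self.beta[list(idx)].copy(), self.platform, self.dataset_id)


@dataclass
class SampleSheet:
    """Per-sample metadata: age, sex, dataset id, subject id, condition.

    Age may be missing (NaN) for prediction-only samples but never for
    training. ``subject_id`` identifies paired/repeated samples (e.g. twins or
    pre/post-intervention biopsies of the same person).
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "age", "sex", "dataset_id")
    OPTIONAL = ("subject_id", "condition")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = pd.NA
        _check_unique(list(df["sample_id"]), "sample ids")
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        if (df["age"].dropna() < 0).any():
            raise ValueError("negative age in sample sheet")
        df["sex"] = df["sex"].fillna("unknown")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels {sorted(bad_sex)}; expected {SEXES}")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    def aligned_to(self, sample_ids: Iterable[str]) -> "SampleSheet":
        """Reorder/subset rows to match ``sample_ids`` exactly."""
        idx = self.df.set_index("sample_id")
        ids = list(sample_ids)
        missing = set(ids) - set(idx.index)
        if missing:
            raise KeyError(f"samples missing from sheet: {sorted(missing)[:5]}")
        return SampleSheet(idx.loc[ids].reset_index())

    def ages(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        sheet = self if sample_ids is None else self.aligned_to(sample_ids)
        return sheet.df["age"].to_numpy(dtype=float)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation.

    ``df`` is indexed by probe id with columns ``chrom``, ``pos`` (1-based),
    ``design_type`` (I/II), ``island_context``, ``chromatin_state``, ``genes``
    (list of symbols), ``is_cg``, ``is_snp_associated``, ``is_multimapping``.
    """

    df: pd.DataFrame

    COLUMNS = (
        "chrom", "pos", "design_type", "island_context", "chromatin_state",
        "genes", "is_cg", "is_snp_associated", "is_multimapping",
    )

    def __post_init__(self) -> None:
        df = self.df
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"probe annotation missing column {col!r}")
        _check_unique(list(df.index), "probe ids")
        if (df["pos"] < 1).any():
            raise ValueError("annotation positions must be >= 1 (1-based)")
        bad = set(df["island_context"]) - set(ISLAND_CONTEXTS)
        if bad:
            raise ValueError(f"unknown island contexts {sorted(bad)}")
        bad = set(df["chromatin_state"]) - set(CHROMATIN_STATES)
        if bad:
            raise ValueError(f"unknown chromatin states {sorted(bad)}")
        bad = set(df["design_type"]) - {"I", "II"}
        if bad:
            raise ValueError(f"unknown design types {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def genes_for(self, probe_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        sub = self.df.loc[self.df.index.intersection(pd.Index(probe_ids))]
        for genes in sub["genes"]:
            out.update(genes)
        return out


@dataclass
class ClockModel:
    """A fitted transformed-age elastic-net clock.

    ``intercept`` and ``weights`` live on the transformed-age scale (see
    :func:`myoclock.clock.transform_age`); ``gold_profile`` stores the
    gold-standard mean beta for every model probe so that predictions can fall
    back to the reference value when a probe is absent from a query dataset.
    """

    intercept: float
    weights: dict[str, float]
    adult_age: float = 20.0
    alpha: float = 0.5
    lambda_: float | None = None
    gold_standard_id: str = ""
    gold_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.adult_age <= 0:
            raise ValueError("adult_age must be > 0")
        for pid, w in self.weights.items():
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for probe {pid}")
            if pid not in self.gold_profile:
                raise ValueError(f"model probe {pid} missing from gold_profile")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights)

    @property
    def n_probes(self) -> int:
        return len(self.weights)


@dataclass
class DMR:
    """A differentially methylated region: >= 2 direction-consistent probes."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    probe_ids: list[str]
    direction: str  # "hyper" | "hypo"
    min_fdr: float
    mean_slope: float  # methylation change per year, averaged over members

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("a DMR needs at least 2 probes")
        if self.end < self.start:
            raise ValueError("DMR end before start")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_beta_matrix(path: str | Path, platform: str, dataset_id: str) -> MethylationDataset:
    """Read a delimited beta matrix (first column ``probe_id``, one column per
    sample). Empty cells become missing values; any value outside [0, 1]
    raises with the offending cell named."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    ds = MethylationDataset(df, platform=platform, dataset_id=dataset_id)
    n_miss = ds.n_missing()
    if n_miss:
        logger.info("%s: %d missing beta values in %s", dataset_id, n_miss, path)
    return ds


def write_beta_matrix(ds: MethylationDataset, path: str | Path) -> None:
    df = ds.beta.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, sep=_sep_for(path), index=False)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation TSV/CSV. ``genes`` is a ``;``-joined list."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    genes = df["genes"].fillna("")
    df["genes"] = [[] if g == "" else g.split(";") for g in genes]
    for col in ("is_cg", "is_snp_associated", "is_multimapping"):
        df[col] = df[col].astype(bool)
    df["pos"] = df["pos"].astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    df = ann.df.copy()
    df["genes"] = [";".join(g) for g in df["genes"]]
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path))


def write_model(model: ClockModel, path: str | Path) -> None:
    """Serialize a clock model as versioned, human-inspectable JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "intercept": model.intercept,
        "adult_age": model.adult_age,
        "alpha": model.alpha,
        "lambda": model.lambda_,
        "gold_standard_id": model.gold_standard_id,
        "weights": model.weights,
        "gold_profile": model.gold_profile,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model(path: str | Path) -> ClockModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unknown model format version {version!r}")
    return ClockModel(
        intercept=float(payload["intercept"]),
        weights={str(k): float(v) for k, v in payload["weights"].items()},
        adult_age=float(payload["adult_age"]),
        alpha=float(payload["alpha"]),
        lambda_=None if payload["lambda"] is None else float(payload["lambda"]),
        gold_standard_id=str(payload["gold_standard_id"]),
        gold_profile={str(k): float(v) for k, v in payload["gold_profile"].items()},
    )


def dmrs_to_bed(dmrs: Sequence[DMR], path: str | Path) -> None:
    """Write DMRs as BED (0-based half-open); score column carries -log10 FDR."""
    lines = []
    for d in dmrs:
        score = min(1000, int(round(-10 * np.log10(max(d.min_fdr, 1e-300)))))
        lines.append(f"{d.chrom}\t{d.start - 1}\t{d.end}\tDMR_{d.direction}\t{score}\t.")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_probes": [len(d.probe_ids) for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "min_fdr": [d.min_fdr for d in dmrs],
            "mean_slope": [d.mean_slope for d in dmrs],
            "probe_ids": [";".join(d.probe_ids) for d in dmrs],
        }
    )
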