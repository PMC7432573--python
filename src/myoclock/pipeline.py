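"""End-to-end pipeline driver with reproducible manifests.

A run is configured by a :class:`RunConfig` (YAML-loadable; unknown keys are
rejected) and executes the toggled stages in order:

    simulate -> qc -> calibrate -> loocv -> train -> ewas -> enrich

Inputs come either from the built-in simulator (default) or from an explicit
list of beta-matrix/sample-sheet paths. Every run writes a ``manifest.json``
recording package/library versions, the seed, the configuration and the
SHA-256 of every artifact, so any result can be reproduced from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acceleration import compute_aa
from .calibrate import calibrate_dataset
from .clock import ClockTrainConfig, loocv, predict_age, train_clock
from .data import (
    MethylationDataset,
    SampleSheet,
    dmrs_to_bed,
    dmrs_to_frame,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_model,
    write_probe_annotation,
    write_sample_sheet,
)
from .ewas import call_dmrs, enrichment_fisher, ewas_fit
from .preprocess import intersect_probes, qc_dataset
from .simulate import default_paper_like_config, simulate_multidataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "calibrate", "loocv", "train", "ewas", "enrich")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the log pointer."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause} (see log section [{stage}])")
        self.stage = stage


@dataclass
class RunConfig:
    """One run's full parameterization."""

    out_dir: str = "myoclock_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulator settings (used when no explicit inputs are given)
    scale: float = 0.5
    common_core_size: int = 5000
    n_age_probes: int = 300
    # clock settings
    alpha: float = 0.5
    n_folds: int = 10
    lambda_rule: str = "min"
    adult_age: float = 20.0
    # ewas settings
    ewas_scale: str = "beta"       # "beta" or "m"
    fdr_cut: float = 0.005
    max_gap: int = 1000
    # explicit inputs: list of {beta, sheet, platform, dataset_id}
    inputs: list[dict[str, str]] | None = None
    annotation: str | None = None
    gold_dataset_id: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def clock_config(self) -> ClockTrainConfig:
        return ClockTrainConfig(alpha=self.alpha, n_folds=self.n_folds,
                                lambda_rule=self.lambda_rule,
                                adult_age=self.adult_age, seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(cfg: RunConfig):
    """Materialize datasets, sheets and annotation for a run (simulator or
    explicit file inputs)."""
    if cfg.inputs:
        datasets = [read_beta_matrix(e["beta"], e["platform"], e["dataset_id"])
                    for e in cfg.inputs]
        sheets = [read_sample_sheet(e["sheet"]) for e in cfg.inputs]
        ann = read_probe_annotation(cfg.annotation) if cfg.annotation else None
        truth = None
    else:
        sim_cfg = default_paper_like_config(
            scale=cfg.scale, common_core_size=cfg.common_core_size,
            n_age_probes=cfg.n_age_probes, seed=cfg.seed)
        datasets, sheets, ann, truth = simulate_multidataset(sim_cfg)
    return datasets, sheets, ann, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the toggled stages; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict[str, Any] = {}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    stage = "simulate"
    try:
        datasets, sheets, ann, truth = load_inputs(cfg)
        if "simulate" in cfg.stages and truth is not None:
            for ds, sheet in zip(datasets, sheets):
                write_beta_matrix(ds, out / f"beta_{ds.dataset_id}.csv")
                write_sample_sheet(sheet, out / f"sheet_{ds.dataset_id}.csv")
                record(out / f"beta_{ds.dataset_id}.csv")
                record(out / f"sheet_{ds.dataset_id}.csv")
            if ann is not None:
                write_probe_annotation(ann, out / "annotation.tsv")
                record(out / "annotation.tsv")

        stage = "qc"
        if "qc" in cfg.stages:
            qc_rows = []
            for ds in datasets:
                if ds.n_samples < 2:
                    continue
                rep = qc_dataset(ds)
                qc_rows.append({"dataset_id": ds.dataset_id,
                                "mean_intercorrelation": rep.mean_intercorrelation,
                                "max_beta": rep.max_beta, "passed": rep.passed})
            pd.DataFrame(qc_rows).to_csv(out / "qc.csv", index=False)
            record(out / "qc.csv")

        datasets = intersect_probes(datasets)
        gold_id = cfg.gold_dataset_id or datasets[0].dataset_id
        gold_ds = next(d for d in datasets if d.dataset_id == gold_id)
        gold_profile = gold_ds.beta.mean(axis=1)

        stage = "calibrate"
        if "calibrate" in cfg.stages:
            datasets = [ds if ds.dataset_id == gold_id
                        else calibrate_dataset(ds, gold_profile)
                        for ds in datasets]

        clock_cfg = cfg.clock_config()
        stage = "loocv"
        if "loocv" in cfg.stages:
            table, loocv_summary = loocv(datasets, sheets, clock_cfg,
                                         gold_profile=gold_profile)
            table.to_csv(out / "loocv_samples.csv", index=False)
            loocv_summary.to_csv(out / "loocv_summary.csv", index=False)
            record(out / "loocv_samples.csv")
            record(out / "loocv_summary.csv")
            summary["loocv_mean_median_abs_aa_diff"] = float(
                loocv_summary["median_abs_aa_diff"].mean())

        model = None
        stage = "train"
        if "train" in cfg.stages:
            model = train_clock(datasets, sheets, clock_cfg,
                                gold_profile=gold_profile,
                                gold_standard_id=gold_id)
            write_model(model, out / "clock_model.json")
            record(out / "clock_model.json")
            summary["n_clock_probes"] = model.n_probes

        ewas_table = None
        stage = "ewas"
        if "ewas" in cfg.stages:
            pooled = pd.concat([ds.beta for ds in datasets], axis=1)
            sheet_all = SampleSheet(pd.concat([s.df for s in sheets],
                                              ignore_index=True))
            values = pooled if cfg.ewas_scale == "beta" else \
                pd.DataFrame(np.log2(pooled.clip(1e-6, 1 - 1e-6)
                                     / (1 - pooled.clip(1e-6, 1 - 1e-6))),
                             index=pooled.index, columns=pooled.columns)
            covs = ["age"]
            if sheet_all.df["sex"].nunique() > 1:
                covs.append("sex")
            if sheet_all.df["dataset_id"].nunique() > 1:
                covs.append("dataset_id")
            ewas_table = ewas_fit(values, sheet_all, covariates=covs)
            ewas_table.rename(columns={"slope": "slope_per_year"}) \
                .rename_axis("probe_id").to_csv(out / "ewas.csv")
            record(out / "ewas.csv")
            summary["n_dmps"] = int((ewas_table["fdr"] < cfg.fdr_cut).sum())
            if ann is not None:
                dmrs = call_dmrs(ewas_table, ann, max_gap=cfg.max_gap,
                                 fdr_cut=cfg.fdr_cut)
                dmrs_to_bed(dmrs, out / "dmrs.bed")
                dmrs_to_frame(dmrs).to_csv(out / "dmrs.csv", index=False)
                record(out / "dmrs.bed")
                record(out / "dmrs.csv")
                summary["n_dmrs"] = len(dmrs)

        stage = "enrich"
        if "enrich" in cfg.stages and model is not None and ann is not None:
            background = list(datasets[0].probe_ids)
            fg = [p for p in model.probe_ids if p in set(background)]
            if fg:
                for category in ("island_context", "chromatin_state"):
                    enr = enrichment_fisher(fg, background, ann, category)
                    enr.to_csv(out / f"enrichment_{category}.csv", index=False)
                    record(out / f"enrichment_{category}.csv")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    manifest = {
        "myoclock_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "artifacts": artifacts,
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def predict_to_frame(model, ds: MethylationDataset,
                     sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Per-sample prediction table: predicted age plus AA statistics when
    actual ages (and an evaluation group) are available."""
    pred = predict_age(model, ds)
    out = pd.DataFrame({"sample_id": pred.index, "predicted_age": pred.to_numpy()})
    if sheet is not None:
        aligned = sheet.aligned_to(pred.index)
        actual = aligned.ages()
        if not np.isnan(actual).all():
            aa = compute_aa(pred.to_numpy(), actual,
                            group_ids=aligned.df["dataset_id"].to_numpy(),
                            sample_ids=list(pred.index))
            out["actual_age"] = actual
            out["aa_diff"] = aa["aa_diff"].to_numpy()
            out["aa_resid"] = aa["aa_resid"].to_numpy()
    return out
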