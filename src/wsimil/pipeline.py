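"""Config-driven end-to-end runner with logging and provenance.

One YAML config describes the whole experiment — data source (synthetic
cohort or a directory of scans plus a manifest), grid geometry, QC
thresholds, CNN schedule, aggregation rule and cross-validation layout —
and :func:`run_pipeline` executes synthesis/ingest -> tiling -> QC ->
training -> aggregation -> evaluation into a run directory containing
the patch index, section predictions, per-task CV reports, a config
snapshot, input hashes and the seed.  A single global seed fans out to
per-stage seeds (derived from the stage name) so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import evaluation, experiments, io, mil, qc, synthetic
from .tiling import GridSpec, tile_scan

log = logging.getLogger("wsimil")


@dataclass
class PipelineConfig:
    out_dir: str
    mode: str = "synth"  # "synth" or "scans"
    seed: int = 0
    tasks: tuple[str, ...] = mil.TASKS
    synth: synthetic.SynthParams = field(default_factory=synthetic.SynthParams)
    scan_dir: str | None = None
    manifest_path: str | None = None
    grid: GridSpec = field(default_factory=experiments.desk_grid)
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    cnn: clf.CNNConfig = field(default_factory=lambda: experiments.desk_cnn_config())
    aggregation: mil.AggregationConfig = field(default_factory=mil.AggregationConfig)
    n_folds: int = 5
    n_val: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "synth" in kw:
            kw["synth"] = synthetic.SynthParams(**_tuplify(kw["synth"]))
        if "grid" in kw:
            kw["grid"] = GridSpec(**kw["grid"])
        if "qc" in kw:
            kw["qc"] = qc.QCConfig(**kw["qc"])
        if "cnn" in kw:
            kw["cnn"] = clf.CNNConfig(**_tuplify(kw["cnn"]))
        if "aggregation" in kw:
            kw["aggregation"] = mil.AggregationConfig(**kw["aggregation"])
        if "tasks" in kw:
            kw["tasks"] = tuple(kw["tasks"])
        return cls(**kw)


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return int(
        np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


def _validate(config: PipelineConfig) -> None:
    if config.mode not in ("synth", "scans"):
        raise ValueError(f"unknown mode {config.mode!r}")
    if config.mode == "scans":
        if not config.scan_dir or not Path(config.scan_dir).is_dir():
            raise ValueError(f"scan_dir {config.scan_dir!r} does not exist")
        if not config.manifest_path or not Path(config.manifest_path).is_file():
            raise ValueError(f"manifest {config.manifest_path!r} does not exist")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    provenance: dict = {"seed": config.seed, "stage_seeds": {}, "inputs": {}}
    for stage in ("synth", "qc", "train"):
        provenance["stage_seeds"][stage] = stage_seed(config.seed, stage)

    if config.mode == "synth":
        params = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "synth"))
        log.info("synthesizing cohort: %d patients x %d scans", params.n_patients, params.scans_per_patient)
        art_model = experiments.train_artifact_filter_on_cohort(
            params, config.grid, seed=stage_seed(config.seed, "qc")
        )
        patches, manifest, qc_reports = experiments.build_patch_dataset(
            params, config.grid, config.qc, artifact_model=art_model
        )
        provenance["inputs"]["synth_params"] = dataclasses.asdict(params)
    else:
        manifest = io.read_manifest(config.manifest_path)
        patches, qc_reports = [], []
        for row in manifest.itertuples(index=False):
            path = _find_scan(Path(config.scan_dir), row.scan_id)
            provenance["inputs"][row.scan_id] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
            pixels = io.load_scan(path)
            records = tile_scan(pixels, row.scan_id, config.grid)
            gray = qc.to_gray(pixels[::4, ::4])
            _, report = qc.qc_scan(records, gray, None, config.qc)
            patches.extend(records)
            qc_reports.append(report)
        log.info("ingested %d scans -> %d patches", len(manifest), len(patches))

    io.write_manifest(out / "manifest.csv", manifest)
    io.write_patch_cache(out / "patches", patches)
    (out / "qc_report.json").write_text(
        json.dumps([{"counts": r.counts, "otsu_threshold": r.otsu_threshold} for r in qc_reports], indent=2)
    )

    cnn_cfg = dataclasses.replace(config.cnn, seed=stage_seed(config.seed, "train"))
    reports = evaluation.cross_validate(
        patches,
        manifest,
        tasks=config.tasks,
        cnn_config=cnn_cfg,
        agg_config=config.aggregation,
        n_folds=config.n_folds,
        n_val=config.n_val,
        seed=stage_seed(config.seed, "train"),
    )
    preds = pd.concat([rep.predictions for rep in reports.values()], ignore_index=True)
    preds.to_csv(out / "section_predictions.csv", index=False)
    from . import plots

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for task, rep in reports.items():
        frame = rep.predictions
        tp, fp, tn, fn = (sum(getattr(f, k) for f in rep.folds) for k in ("tp", "fp", "tn", "fn"))
        plots.confusion_matrix_png(tp, fp, tn, fn, fig_dir / f"confusion_{task}.png", title=task)
        plots.roc_png(frame["true_label"], frame["score"], fig_dir / f"roc_{task}.png", title=task)
    evaluation.report_frame(reports).to_csv(out / "cv_summary.csv", index=False)
    (out / "cv_report.json").write_text(json.dumps(_reports_json(reports), indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(_config_snapshot(config)))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("run complete: %s", out)
    return out


def _find_scan(scan_dir: Path, scan_id: str) -> Path:
    for ext in (".png", ".tif", ".tiff"):
        p = scan_dir / f"{scan_id}{ext}"
        if p.is_file():
            return p
    raise FileNotFoundError(f"no scan image for {scan_id!r} in {scan_dir}")


def _reports_json(reports: dict[str, evaluation.CVReport]) -> dict:
    out = {}
    for task, rep in reports.items():
        out[task] = {
            "mean": rep.mean,
            "sd": rep.sd,
            "n_undefined": rep.n_undefined,
            "folds": [
                {
                    "fold": f.fold_index,
                    "confusion": {"tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn},
                    "metrics": f.metrics,
                    "n_sections": f.n_sections,
                    "n_no_call": f.n_no_call,
                }
                for f in rep.folds
            ],
        }
    return out


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["tasks"] = list(config.tasks)
    return json.loads(json.dumps(snap, default=lambda o: list(o) if isinstance(o, tuple) else str(o)))
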