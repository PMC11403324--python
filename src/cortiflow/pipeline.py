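"""End-to-end orchestration: raw (or simulated) samples -> QC -> indices ->
mixed models -> complication tests, with a hashed artifact manifest.

Reruns with the same configuration and seed are byte-identical for every
CSV/JSON artifact; only the manifest timestamp differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cortiflow
from cortiflow.config import SimConfig
from cortiflow.simulate import simulate_cohort
from cortiflow.qc import run_qc
from cortiflow.indices import compute_indices, stage_descriptives
from cortiflow.lmm import ModelSpec, MixedLMM
from cortiflow.models import (
    make_morning_spec,
    make_diurnal_spec,
    morning_rows,
    diurnal_rows,
    select_structure,
    icc_from_components,
)
from cortiflow.complications import test_complication, FINAL_STRUCTURE

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "subject_id", "stage", "occasion", "raw_dup1", "raw_dup2",
    "clock_time", "date", "awakening_time", "rose_before_S1",
    "ill_on_day", "plate_id",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    output_dir: str = "cortiflow_run"
    seed: int = 0
    # either simulate (SimConfig dict or None for defaults) ...
    simulate: dict | None = None
    # ... or read the long-format CSVs
    samples_path: str | None = None
    subjects_path: str | None = None
    models: tuple = ("morning", "diurnal")
    do_select_structure: bool = False
    structure: dict | None = None  # overrides FINAL_STRUCTURE for both models
    complications: tuple = ()  # subset of ("bmi", "hypertensive", "gdm")
    adjusted_complications: bool = False
    log_level: str = "INFO"

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        for k in ("models", "complications"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def validate_samples_schema(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"samples table is missing required columns: {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    status = {"stages": {}, "failed": None}

    def write_df(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        artifacts.append(p)

    def write_json(obj, name: str):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        artifacts.append(p)

    try:
        # -- input ---------------------------------------------------------
        if cfg.simulate is not None or cfg.samples_path is None:
            sim = SimConfig.from_dict(cfg.simulate) if cfg.simulate else SimConfig()
            cohort = simulate_cohort(sim, seed=cfg.seed)
            samples, subjects = cohort.samples, cohort.subjects
            write_json(
                {
                    "violations": {
                        k: len(v) for k, v in cohort.truth["violations"].items()
                    },
                    "violation_sample_counts": cohort.truth["violation_sample_counts"],
                },
                "truth_ledger.json",
            )
            write_df(samples, "samples.csv")
            write_df(subjects, "subjects.csv")
        else:
            samples = pd.read_csv(cfg.samples_path)
            subjects = pd.read_csv(cfg.subjects_path)
        validate_samples_schema(samples)
        status["stages"]["input"] = "ok"

        # -- QC -------------------------------------------------------------
        table, report = run_qc(samples, subjects)
        write_df(table, "analysis_table.csv")
        (out / "qc_report.json").write_text(report.to_json())
        artifacts.append(out / "qc_report.json")
        (out / "qc_report.txt").write_text(report.to_text())
        status["stages"]["qc"] = "ok"

        # -- indices ---------------------------------------------------------
        idx = compute_indices(table)
        write_df(idx, "indices.csv")
        desc = stage_descriptives(table, idx)
        write_df(desc["occasions"], "stage_occasions.csv")
        write_df(desc["indices"], "stage_indices.csv")
        write_json(
            {
                "participation": desc["participation"],
                "cross_stage_icc": desc["cross_stage_icc"],
            },
            "stage_summary.json",
        )
        status["stages"]["indices"] = "ok"

        # -- mixed models ----------------------------------------------------
        iccs = {}
        for model in cfg.models:
            rows = morning_rows(table) if model == "morning" else diurnal_rows(table)
            spec = make_morning_spec() if model == "morning" else make_diurnal_spec()
            if cfg.do_select_structure:
                fit, trace = select_structure(spec, rows)
                write_json(trace, f"{model}_ladder.json")
            else:
                struct = cfg.structure or FINAL_STRUCTURE[model]
                fit = MixedLMM.from_dataframe(rows, spec.replace(**struct)).fit()
            coef = fit.fe_table()
            coef.to_csv(out / f"{model}_model.csv", index=False)
            artifacts.append(out / f"{model}_model.csv")
            fit.vc_table().to_csv(out / f"{model}_variance_components.csv", index=False)
            artifacts.append(out / f"{model}_variance_components.csv")
            icc = icc_from_components(fit.vc)
            iccs[model] = {
                "throughout": icc.icc_throughout,
                "within_stage": icc.icc_within_stage,
                "formula_id": icc.formula_id,
            }
            status["stages"][f"model:{model}"] = "ok"
        if iccs:
            write_json(iccs, "icc.json")

        # -- complications ---------------------------------------------------
        if cfg.complications:
            comp_dir = out / "complications"
            comp_dir.mkdir(exist_ok=True)
            for model in cfg.models:
                for expo in cfg.complications:
                    res = test_complication(
                        expo, model, table,
                        adjusted=cfg.adjusted_complications,
                        structure=cfg.structure,
                    )
                    p = comp_dir / f"{model}_{expo}.csv"
                    res.table.to_csv(p, index=False)
                    artifacts.append(p)
            status["stages"]["complications"] = "ok"
    except Exception as exc:
        status["failed"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, cfg, artifacts, status)
        raise
    _write_manifest(out, cfg, artifacts, status)
    return out


def _write_manifest(out: Path, cfg: RunConfig, artifacts: list[Path], status: dict):
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    manifest = {
        "version": cortiflow.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts if p.exists()
        },
        "status": status,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def verify_manifest(run_dir: str | Path) -> bool:
    """Recompute artifact hashes and compare with the manifest."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    for name, digest in manifest["artifacts"].items():
        p = run_dir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
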