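"""Stage orchestration: simulate -> calibrate -> preprocess -> fit -> recover.

Each stage reads and writes plain CSV/JSON, so any stage can be re-run from
its on-disk inputs and reproduces its outputs bit-exactly for a fixed seed.
A run manifest records the seed, package versions, per-stage status,
timings and output-file hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate_dataset
from .catchment_models import fit_all_catchments
from .data_model import (
    apply_felling_truncation,
    load_dataset,
    records_to_frame,
    write_dataset,
)
from .hierarchical import build_design, fit_hierarchical, marginal_anova
from .preprocessing import age_class_summary, compute_responses, responses_to_frame
from .recovery import analyze_recovery, response_group_tests
from .synthetic import GeneratorConfig, write_simulation

logger = logging.getLogger("forestflow")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Plain-text configuration for a full pipeline run."""

    work_dir: str = "."
    meta_path: str = "catchments.csv"
    annual_path: str = "annual.csv"
    seed: int = 1
    simulate: bool = False
    n_catchments: int = 43
    scenario: str = "model"
    run_calibrate: bool = True
    run_preprocess: bool = True
    run_catchment_fits: bool = True
    run_hierarchical: bool = True
    run_recovery: bool = True
    variant: str = "base"
    method: str = "reml"
    age_class_step: float = 5.0
    age_class_window: float = 0.5
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_row(fit) -> dict:
    return {
        "catchment_id": fit.catchment_id,
        "form": fit.form,
        "classification": fit.classification,
        "aic": fit.aic,
        "r2_adj": fit.r2_adj,
        "n": fit.n,
        **{f"coef_{k}": v for k, v in fit.coefs.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    work = Path(config.work_dir)
    work.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "forestflow",
        "version": __version__,
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": [],
    }
    outputs: dict[str, Path] = {}

    def stage(name: str, enabled: bool, fn) -> bool:
        entry = {"stage": name, "status": "skipped"}
        if not enabled:
            manifest["stages"].append(entry)
            return True
        t0 = time.perf_counter()
        try:
            produced = fn() or {}
            entry["status"] = "ok"
            entry["outputs"] = {
                key: {"path": str(p), "sha256": _sha256(p)} for key, p in produced.items()
            }
            outputs.update(produced)
        except Exception as exc:  # stage failure recorded, downstream skipped
            logger.error("stage %s failed: %s", name, exc)
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            manifest["stages"].append(entry)
            entry["seconds"] = round(time.perf_counter() - t0, 3)
            return False
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)
        return True

    state: dict = {}

    def do_simulate():
        gen = GeneratorConfig(
            seed=config.seed, n_catchments=config.n_catchments, scenario=config.scenario
        )
        paths = write_simulation(gen, work)
        return paths

    def do_calibrate():
        meta_path = work / config.meta_path if config.simulate else Path(config.meta_path)
        annual_path = work / config.annual_path if config.simulate else Path(config.annual_path)
        meta, records = load_dataset(str(meta_path), str(annual_path))
        records = apply_felling_truncation(records)
        calibrated, log = calibrate_dataset(meta, records)
        out = work / "annual_calibrated.csv"
        records_to_frame(calibrated).to_csv(out, index=False)
        log_path = work / "calibration_log.csv"
        log.to_csv(log_path, index=False)
        state["meta"] = meta
        state["records"] = calibrated
        return {"annual_calibrated": out, "calibration_log": log_path}

    def do_preprocess():
        responses = compute_responses(state["meta"], state["records"])
        df = responses_to_frame(responses)
        out = work / "responses_computed.csv"
        df.to_csv(out, index=False)
        summary = age_class_summary(
            responses, step=config.age_class_step, window=config.age_class_window
        )
        sm = pd.DataFrame([dataclasses.asdict(s) for s in summary])
        sm_path = work / "age_class_summary.csv"
        sm.to_csv(sm_path, index=False)
        state["responses"] = df
        return {"responses": out, "age_class_summary": sm_path}

    def do_catchment_fits():
        usable = state["responses"].groupby("catchment_id").filter(lambda g: len(g) >= 3)
        fits = fit_all_catchments(usable)
        state["fits"] = fits
        df = pd.DataFrame([_fit_row(f) for f in fits])
        out = work / "catchment_fits.csv"
        df.to_csv(out, index=False)
        return {"catchment_fits": out}

    def do_hierarchical():
        design = build_design(state["meta"], state["responses"], config.variant)
        fit = fit_hierarchical(design, method=config.method)
        anova = marginal_anova(fit)
        payload = {
            "variant": fit.variant,
            "method": fit.method,
            "coefficients": fit.coefficients,
            "fixed_se": {
                name: float(np.sqrt(fit.fixed_vcov[i, i]))
                for i, name in enumerate(fit.beta_names)
            },
            "random": {
                "sds": fit.random.sds.tolist(),
                "corr": fit.random.corr.tolist(),
                "phi": fit.random.phi.tolist(),
                "sigma": fit.random.sigma,
            },
            "loglik": fit.loglik,
            "aic": fit.aic,
            "n_obs": fit.n_obs,
            "n_catchments": fit.n_catchments,
            "anova": anova.to_dict(orient="records"),
        }
        out = work / "hierarchical_fit.json"
        out.write_text(json.dumps(payload, indent=2))
        state["hier"] = fit
        return {"hierarchical_fit": out}

    def do_recovery():
        if "fits" not in state:
            raise RuntimeError("recovery requires catchment fits")
        results = analyze_recovery(state["responses"], state["fits"])
        rows = []
        for r in results:
            d = dataclasses.asdict(r)
            for key in ("q_at_min_ci", "q_at_final_ci"):
                ci = d.pop(key)
                d[f"{key}_lo"] = ci[0] if ci else None
                d[f"{key}_hi"] = ci[1] if ci else None
            rows.append(d)
        out = work / "recovery.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        tests = response_group_tests(state["fits"])
        tests_path = work / "group_tests.json"
        tests_path.write_text(json.dumps(tests, indent=2))
        counts = pd.Series(
            [f.classification or "none" for f in state["fits"]]
        ).value_counts().to_dict()
        summary_path = work / "classification_counts.json"
        summary_path.write_text(json.dumps(counts, indent=2))
        return {"recovery": out, "group_tests": tests_path, "classification_counts": summary_path}

    ok = stage("simulate", config.simulate, do_simulate)
    ok = stage("calibrate", config.run_calibrate and ok, do_calibrate) and ok
    ok = stage("preprocess", config.run_preprocess and ok, do_preprocess) and ok
    fits_ok = stage("fit-catchments", config.run_catchment_fits and ok, do_catchment_fits) and ok
    stage("fit-hierarchical", config.run_hierarchical and ok, do_hierarchical)
    stage("recovery", config.run_recovery and fits_ok, do_recovery)

    manifest_path = work / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
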