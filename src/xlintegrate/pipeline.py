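"""End-to-end pipeline orchestration from a single YAML config.

A run executes a declared list of stages in order (synthetic generation,
ensemble satisfaction scoring, restraint-driven collapse, size
estimation), writes artifacts under an output directory, and records a
machine-readable manifest whose metrics are reproducible for identical
config + inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .collapse_model import Restraint, build_expanded_chain, collapse, \
    restraint_satisfaction
from .ensemble_satisfaction import score_ensemble
from .hydrodynamics import kirkwood_rh, radius_of_gyration, \
    mfk_hydrodynamic_radius
from .synthetic_data import gen_chain, gen_ensemble, plant_crosslinks
from .xl_tables import write_xl_table

KNOWN_STAGES = ("generate", "score", "collapse", "size")


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Schema check; raises ConfigError before any stage runs."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in ("seed", "stages"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")
    if not isinstance(config["seed"], int):
        raise ConfigError("seed must be an integer")
    stages = config["stages"]
    if not isinstance(stages, list) or not stages:
        raise ConfigError("stages must be a non-empty list")
    for stage in stages:
        if stage not in KNOWN_STAGES:
            raise ConfigError(
                f"unknown stage {stage!r}; known: {KNOWN_STAGES}")
    order = [KNOWN_STAGES.index(s) for s in stages]
    if order != sorted(order):
        raise ConfigError("stages must respect dependency order "
                          f"{KNOWN_STAGES}")
    params = config.get("params", {})
    if not isinstance(params, dict):
        raise ConfigError("params must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    version: str
    metrics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "stages": self.stages, "version": self.version,
            "metrics": self.metrics, "artifacts": self.artifacts,
            "completed_stages": self.completed_stages,
            "failed_stage": self.failed_stage,
        }


def run_pipeline(config: dict, outdir: str | Path,
                 log_stream=None) -> RunManifest:
    """Execute the configured stages; halt on first failure with a
    manifest recording the completed stages."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    params = config.get("params", {})
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=seed,
        stages=list(config["stages"]), version=__version__)

    def log(event: str, **fields) -> None:
        if log_stream is not None:
            print(json.dumps({"ts": time.time(), "event": event, **fields}),
                  file=log_stream)

    state: dict = {}
    try:
        for stage in config["stages"]:
            log("stage_start", stage=stage)
            if stage == "generate":
                n = int(params.get("n_residues", 60))
                chain = gen_chain(n, seed, params.get("compactness", 0.5))
                ensemble = gen_ensemble(
                    chain, int(params.get("n_models", 20)),
                    float(params.get("jitter", 1.0)), seed)
                links, truth = plant_crosslinks(
                    ensemble.models[0], params.get("chemistry", "DMTMM"),
                    int(params.get("n_true", 5)),
                    int(params.get("n_decoy", 5)), seed)
                xl_path = outdir / "links.tsv"
                write_xl_table(links, str(xl_path))
                state.update(chain=chain, ensemble=ensemble, links=links,
                             truth=truth)
                manifest.artifacts["links"] = str(xl_path)
                manifest.metrics["generate"] = {
                    "n_residues": n, "n_models": len(ensemble),
                    "n_links": len(links)}
            elif stage == "score":
                report = score_ensemble(state["links"], state["ensemble"])
                manifest.metrics["score"] = {
                    "best_models": report.best_models,
                    "best_count": int(report.per_model_counts.max()),
                    "histogram": report.histogram()}
            elif stage == "collapse":
                n = state["chain"].n_beads if "chain" in state else \
                    int(params.get("n_residues", 60))
                expanded = build_expanded_chain(n)
                truth = state.get("truth", {})
                restraints = [
                    Restraint(a - 1, b - 1,
                              16.0 if params.get("chemistry", "DMTMM")
                              == "DMTMM" else 21.0)
                    for (a, b), is_true in truth.items() if is_true
                ]
                result = collapse(expanded, restraints, seed=seed,
                                  max_iter=int(params.get("max_iter", 1500)))
                state["collapsed"] = result.chain
                state["expanded"] = expanded
                manifest.metrics["collapse"] = {
                    **result.summary(),
                    "restraint_satisfaction": restraint_satisfaction(
                        result.chain, restraints)}
            elif stage == "size":
                sizes = {}
                if "expanded" in state:
                    sizes["expanded_rg_nm"] = radius_of_gyration(
                        state["expanded"].coords)
                    sizes["expanded_rh_nm"] = kirkwood_rh(
                        state["expanded"].coords)
                if "collapsed" in state:
                    sizes["collapsed_rg_nm"] = radius_of_gyration(
                        state["collapsed"].coords)
                    sizes["collapsed_rh_nm"] = kirkwood_rh(
                        state["collapsed"].coords)
                n = int(params.get("n_residues", 60))
                sizes["mfk_disordered_rh_nm"] = mfk_hydrodynamic_radius(n)
                manifest.metrics["size"] = sizes
            manifest.completed_stages.append(stage)
            log("stage_done", stage=stage)
    except Exception as exc:
        manifest.failed_stage = stage
        log("stage_failed", stage=stage, error=str(exc))
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: RunManifest, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, default=str)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
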