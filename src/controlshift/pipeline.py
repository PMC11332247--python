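"""End-to-end orchestration: simulate -> preprocess -> fit -> caf/stats/optimality.

A run is described by a JSON/YAML-free pydantic-validated config.  Each
stage draws its randomness from a named substream of the root seed, so
enabling or disabling one stage never perturbs another stage's draws, and a
rerun with the same config reproduces byte-identical data outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import caf as caf_mod
from . import design, fitting, group_stats, optimality, preprocessing
from .trialtable import read_trials, write_trials


class SimulateConfig(BaseModel):
    experiment: int = Field(ge=1, le=3)
    n_subjects_per_group: int = Field(ge=1)
    model: str = "ddm_shift"
    trials_per_block: int | None = Field(default=None, ge=2)
    n_blocks: int | None = Field(default=None, ge=1)


class FitConfig(BaseModel):
    model: str = "ddm_shift"


class StatsConfig(BaseModel):
    parameter: str = "shift_delta"


class OptimalityConfig(BaseModel):
    n_trials: int = Field(default=2000, ge=1)


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "run_output"
    profile: str = Field(default="ci", pattern="^(ci|full)$")
    simulate: SimulateConfig
    preprocess: bool = True
    fit: FitConfig | None = None
    caf: bool = False
    stats: StatsConfig | None = None
    optimality: OptimalityConfig | None = None


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    package_version: str
    files: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the root seed and the stage name."""
    return int(np.random.SeedSequence(
        [root_seed, zlib.crc32(stage.encode())]).generate_state(1)[0])


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        raise ValueError(f"invalid pipeline config: {err}") from err


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute the configured stages in dependency order and write a manifest."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config.model_dump(), sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical).hexdigest(),
        seeds={}, package_version=__version__,
        started=datetime.now(timezone.utc).isoformat())

    def _record(path):
        manifest.files.append(str(path))

    profile_optimizer = (fitting.CI_OPTIMIZER if config.profile == "ci"
                         else fitting.FULL_OPTIMIZER)

    # --- simulate -------------------------------------------------------
    sim_cfg = config.simulate
    overrides = {}
    if sim_cfg.trials_per_block is not None:
        overrides["trials_per_block"] = sim_cfg.trials_per_block
    if sim_cfg.n_blocks is not None:
        overrides["n_blocks"] = sim_cfg.n_blocks
    exp = design.experiment_config(sim_cfg.experiment, **overrides)
    seed = stage_seed(config.seed, "simulate")
    manifest.seeds["simulate"] = seed
    spec = design.CohortSpec(n_subjects_per_group=sim_cfg.n_subjects_per_group,
                             model=sim_cfg.model, seed=seed)
    trials, _true = design.generate_cohort(spec, exp)
    trials_path = out / "trials.tsv"
    write_trials(trials, trials_path)
    _record(trials_path)

    # --- preprocess -----------------------------------------------------
    acc_table = rt_table = None
    if config.preprocess:
        kept, subj_report = preprocessing.exclude_subjects(trials)
        acc_table, acc_report = preprocessing.filter_trials(kept, "accuracy")
        rt_table, rt_report = preprocessing.filter_trials(kept, "rt")
        for name, table in (("accuracy", acc_table), ("rt", rt_table)):
            path = out / f"trials_{name}_stream.tsv"
            write_trials(table, path)
            _record(path)
        report_path = out / "exclusions.json"
        with open(report_path, "w") as fh:
            json.dump({"subjects": subj_report.__dict__,
                       "accuracy_stream": acc_report.__dict__,
                       "rt_stream": rt_report.__dict__}, fh, indent=2)
        _record(report_path)
        effects, _summary = preprocessing.congruency_effects(acc_table, rt_table)
        effects_path = out / "congruency_effects.tsv"
        effects.to_csv(effects_path, sep="\t", index=False)
        _record(effects_path)

    # --- fit ------------------------------------------------------------
    param_table = None
    if config.fit is not None:
        if acc_table is None:
            raise RuntimeError("fit stage requires the preprocess stage")
        seed = stage_seed(config.seed, "fit")
        manifest.seeds["fit"] = seed
        fit_input = acc_table  # rt stream with errors retained == accuracy stream
        fits, param_table = fitting.fit_cohort(fit_input, config.fit.model,
                                               seed=seed,
                                               optimizer=profile_optimizer)
        params_path = out / "fitted_params.tsv"
        param_table.to_csv(params_path, sep="\t", index=False)
        _record(params_path)

    # --- caf ------------------------------------------------------------
    if config.caf:
        source = acc_table if acc_table is not None else trials
        table = caf_mod.conditional_accuracy(source)
        caf_path = out / "caf.tsv"
        table.to_csv(caf_path, sep="\t", index=False)
        _record(caf_path)

    # --- stats ----------------------------------------------------------
    if config.stats is not None:
        if param_table is None:
            raise RuntimeError("stats stage requires the fit stage")
        result = group_stats.compare_groups(param_table,
                                            parameter=config.stats.parameter)
        stats_path = out / "group_stats.json"
        with open(stats_path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        _record(stats_path)

    # --- optimality -----------------------------------------------------
    if config.optimality is not None:
        seed = stage_seed(config.seed, "optimality")
        manifest.seeds["optimality"] = seed
        base = design.DEFAULT_POPULATION["ddm_shift"]
        base_params = fitting.make_params(
            "ddm_shift", {k: mean for k, (mean, _sd) in base.items()})
        grid = optimality.sweep_grid(base_params, exp,
                                     n_trials=config.optimality.n_trials,
                                     seed=seed)
        for path in optimality.write_grid(grid, out / "optimality"):
            _record(path)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    _record(out / "manifest.json")
    return manifest
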