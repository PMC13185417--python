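"""End-to-end orchestration: configs, seeds, manifests, and the demo study.

``run_demo`` reproduces the design of the cell-imaging experiments on
synthetic data: untreated cells plus two G4 ligands, each with and without
pre-treatment by a G4-destabilising helicase mimic, quantified over several
independent experiments with segmentation parameters frozen per experiment,
followed by a drug-pair viability matrix scored against Bliss independence.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__
from .foci import (
    cells_to_frame,
    estimate_foci_threshold,
    flag_outliers,
    quantify_cell,
    subtract_background,
    summarize_condition,
)
from .simulate import (
    SimulationConfig,
    simulate_cell_stack,
    simulate_synergy_matrix,
)
from .synergy import bliss_score_matrix, synergy_report

__all__ = [
    "RunConfig",
    "RunManifest",
    "validate_config",
    "run_demo",
    "run_tasq_study",
    "write_outputs",
    "DEMO_CONDITION_FOLDS",
]

#: planted fold changes of the demo imaging study, one per treatment arm:
#: two G4 ligands raise nuclear foci strongly, helicase pre-treatment
#: blunts the ligand effect while slightly raising the baseline.
DEMO_CONDITION_FOLDS = {
    "NT": 1.0,
    "PDS": 3.8,
    "QN-302": 4.5,
    "PhpC": 1.5,
    "PDS+PhpC": 1.6,
    "QN-302+PhpC": 1.8,
}

_ALLOWED_UNITS = {"nM", "uM", "µM", "mM", "°C", "C", "%"}


class ConfigError(ValueError):
    pass


class RunConfig(BaseModel):
    """Validated run configuration.

    ``experiment_params`` maps experiment id -> segmentation-params id; a
    params id shared between experiments violates the frozen-parameters
    rule and is rejected unless ``allow_params_reuse`` is set.
    """

    mode: Literal["tasq", "gh2ax", "srb", "fqa", "melt", "synergy", "demo"] = "demo"
    seed: int = 0
    input_paths: list[str] = Field(default_factory=list)
    out_dir: str | None = None
    units: dict[str, str] = Field(default_factory=dict)
    experiment_params: dict[str, str] = Field(default_factory=dict)
    allow_params_reuse: bool = False
    n_cells: int = Field(30, ge=1)
    n_experiments: int = Field(3, ge=1)
    version: str = __version__

    @field_validator("units")
    @classmethod
    def _units_known(cls, v: dict[str, str]) -> dict[str, str]:
        bad = {k: u for k, u in v.items() if u not in _ALLOWED_UNITS}
        if bad:
            raise ValueError(f"unsupported units {bad}; allowed: {sorted(_ALLOWED_UNITS)}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for p in self.input_paths:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if not self.allow_params_reuse:
            ids = list(self.experiment_params.values())
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ValueError(
                    f"segmentation params {sorted(dupes)} shared across experiments; "
                    "parameters must be frozen per experiment (allow_params_reuse overrides)"
                )
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-check a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} does not parse to a mapping")
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


@dataclass
class RunManifest:
    """Reproducibility record written next to every result set."""

    input_hashes: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dict(self, include_timings: bool = True) -> dict:
        d = {
            "input_hashes": self.input_hashes,
            "parameters": self.parameters,
            "warnings": self.warnings,
            "version": self.version,
        }
        if include_timings:
            d["timings_s"] = self.timings_s
        return d


def hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def write_outputs(
    results: dict[str, "pd.DataFrame | dict"],
    manifest: RunManifest,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write result tables (CSV) and mappings (JSON) atomically, plus the manifest.

    DataFrames become ``<name>.csv``; dicts become ``<name>.json`` with
    sorted keys, so identical results always produce identical bytes
    (manifest timings excepted).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            tmp = path.with_suffix(".csv.tmp")
            obj.to_csv(tmp, index=False, float_format="%.8g")
            tmp.replace(path)
        else:
            path = out_dir / f"{name}.json"
            _atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True, default=str))
        written[name] = path
    mpath = out_dir / "manifest.json"
    _atomic_write_text(mpath, json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    written["manifest"] = mpath
    return written


# ------------------------------------------------------------------ studies

def run_tasq_study(
    seed: int,
    condition_folds: dict[str, float] | None = None,
    n_experiments: int = 3,
    n_cells: int = 30,
    mode: str = "tasq",
    metric: str = "nuclear",
    base_config: dict | None = None,
) -> tuple[pd.DataFrame, list]:
    """Simulate and quantify a multi-condition, multi-experiment foci study.

    Per experiment: generate ``n_cells`` stacks per condition with the
    planted fold changes, subtract each cell's own cell-free background,
    freeze the foci threshold on the untreated fields, quantify every cell
    with those frozen parameters, and flag outliers. Returns the tidy
    per-cell table and the condition summaries (experiment-level means
    first, then across-experiment statistics).
    """
    condition_folds = condition_folds or DEMO_CONDITION_FOLDS
    if "NT" not in condition_folds:
        raise ConfigError("the study design needs an untreated (NT) condition")
    base_config = base_config or {}
    seeds = np.random.SeedSequence(seed)
    cell_seed = iter(seeds.generate_state(n_experiments * len(condition_folds) * n_cells * 2))

    all_cells: dict[tuple[str, str], list] = {}
    for e in range(1, n_experiments + 1):
        exp_id = f"exp{e}"
        # generate and background-subtract every cell of this experiment
        per_condition: dict[str, list] = {}
        for cond, fold in condition_folds.items():
            items = []
            for _ in range(n_cells):
                cfg = SimulationConfig(
                    fold_change=fold, seed=int(next(cell_seed) % 2**31), **base_config
                )
                stack, truth = simulate_cell_stack(cfg)
                stack = subtract_background(stack, ~truth.cell_mask)
                items.append((stack, truth))
            per_condition[cond] = items
        params = estimate_foci_threshold(
            [s for s, _ in per_condition["NT"]], experiment_id=exp_id
        )
        for cond, items in per_condition.items():
            quants = [
                quantify_cell(
                    stack, truth.roi(f"{exp_id}-{cond}-{i}"), params,
                    mode=mode, experiment_id=exp_id,
                )
                for i, (stack, truth) in enumerate(items)
            ]
            all_cells[(cond, exp_id)] = flag_outliers(quants, mode=mode)

    frame = cells_to_frame(all_cells, metric=metric)
    summaries = summarize_condition(frame, nt_label="NT", metric=metric)
    return frame, summaries


def run_demo(
    seed: int,
    out_dir: str | Path | None = None,
    n_experiments: int = 3,
    n_cells: int = 30,
    planted_excess: float = 20.0,
) -> dict:
    """Full synthetic study: imaging arms plus a Bliss synergy matrix.

    Returns a dict with the per-cell table, condition summaries, the scored
    synergy matrix and (when ``out_dir`` is given) the written file paths.
    Deterministic for a fixed seed.
    """
    t0 = time.perf_counter()
    manifest = RunManifest(
        parameters={
            "seed": seed,
            "n_experiments": n_experiments,
            "n_cells": n_cells,
            "condition_folds": DEMO_CONDITION_FOLDS,
            "planted_excess": planted_excess,
        }
    )
    frame, summaries = run_tasq_study(
        seed, n_experiments=n_experiments, n_cells=n_cells
    )
    manifest.timings_s["imaging"] = round(time.perf_counter() - t0, 3)

    t1 = time.perf_counter()
    matrix_table = simulate_synergy_matrix(
        {"bottom": 5.0, "top": 100.0, "mid": 4.2, "hill": 1.2, "unit": "nM"},
        {"bottom": 10.0, "top": 100.0, "mid": 51.9, "hill": 1.0, "unit": "uM"},
        planted_excess=planted_excess,
        noise_cv=0.05,
        replicates=3,
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31),
    )
    matrix = bliss_score_matrix(matrix_table)
    manifest.timings_s["synergy"] = round(time.perf_counter() - t1, 3)

    summary_table = pd.DataFrame(
        [
            {
                "condition": s.condition,
                "metric": s.metric,
                "mean": s.mean,
                "sd": s.sd,
                "fold_change": s.fold_change,
                "delta": s.delta,
                "n_cells": s.n_cells,
            }
            for s in summaries
        ]
    )
    result = {
        "per_cell": frame,
        "summaries": summaries,
        "summary_table": summary_table,
        "synergy": matrix,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        written = write_outputs(
            {"per_cell": frame, "condition_summaries": summary_table},
            manifest,
            out_dir,
        )
        written.update(
            synergy_report(
                matrix, out_dir / "synergy", provenance={"seed": seed}
            )
        )
        result["paths"] = written
    return result
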