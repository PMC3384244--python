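"""YAML/JSON configuration for the pipeline.

A config file has flat ``parameters`` (CircuitParameters fields), a list of
``variants`` blocks (label, promoter_scale, rbs_scale), a ``schedule``
block, and optional ``solver``, ``noise``, ``clone_variability``, ``fit``,
``sensitivity``, ``crossval`` and ``stages`` sections.  Validation errors
carry the offending key path and, where possible, the line in the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dde import SolverSettings
from .model import CircuitParameters, FeedbackVariant, InductionSchedule

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    parameters: CircuitParameters
    variants: dict
    schedule: InductionSchedule
    solver: SolverSettings
    noise: "object | None" = None
    clone_variability: "object | None" = None
    stages: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None
    sampling_times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 12.5, 0.5))
    n_clones: int = 4
    fit_free: list = field(default_factory=lambda: ["k_tx_R", "K_tetR", "k_agg"])
    fit_bounds: dict | None = None
    fit_n_starts: int = 20
    sensitivity_variant: str = "WT_STRONG"
    sensitivity_perturbation: float = 0.05
    crossval_k: int = 4
    crossval_unit: str = "clone"
    crossval_n_starts: int = 4


def _find_line(path: Path, key: str) -> str:
    try:
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if line.strip().startswith(f"{key}:") or f" {key}:" in line:
                return f" (line {i})"
    except OSError:
        pass
    return ""


def _section(raw: dict, name: str, path: Path) -> dict:
    val = raw.get(name, {}) or {}
    if not isinstance(val, dict):
        raise ConfigError(f"section {name!r} must be a mapping{_find_line(path, name)}")
    return val


def load_config(config_path) -> PipelineConfig:
    """Parse and validate a pipeline config (YAML or JSON)."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")

    known_top = {
        "parameters", "variants", "schedule", "solver", "noise", "clone_variability",
        "stages", "seed", "out_dir", "generate", "fit", "sensitivity", "crossval",
    }
    for key in raw:
        if key not in known_top:
            raise ConfigError(f"unknown config section {key!r}{_find_line(path, key)}")

    try:
        params = CircuitParameters.from_dict(_section(raw, "parameters", path))
    except Exception as exc:
        raise ConfigError(f"parameters: {exc}{_find_line(path, 'parameters')}") from exc

    vblocks = raw.get("variants")
    if not vblocks:
        from .model import STANDARD_VARIANTS

        variants = dict(STANDARD_VARIANTS)
    else:
        if not isinstance(vblocks, list):
            raise ConfigError(f"'variants' must be a list of blocks{_find_line(path, 'variants')}")
        variants = {}
        for block in vblocks:
            try:
                v = FeedbackVariant(
                    label=block["label"],
                    promoter_scale=float(block.get("promoter_scale", 1.0)),
                    rbs_scale=float(block.get("rbs_scale", 1.0)),
                )
            except Exception as exc:
                raise ConfigError(f"variants: {exc}{_find_line(path, 'label')}") from exc
            variants[v.label] = v

    try:
        schedule = InductionSchedule(**_section(raw, "schedule", path))
    except Exception as exc:
        raise ConfigError(f"schedule: {exc}{_find_line(path, 'schedule')}") from exc
    try:
        solver = SolverSettings(**_section(raw, "solver", path))
    except Exception as exc:
        raise ConfigError(f"solver: {exc}{_find_line(path, 'solver')}") from exc

    noise = clone_var = None
    if "noise" in raw:
        from .synth import NoiseModel

        try:
            noise = NoiseModel(**_section(raw, "noise", path))
        except Exception as exc:
            raise ConfigError(f"noise: {exc}{_find_line(path, 'noise')}") from exc
    if "clone_variability" in raw:
        from .synth import CloneVariabilityModel

        try:
            clone_var = CloneVariabilityModel(**_section(raw, "clone_variability", path))
        except Exception as exc:
            raise ConfigError(
                f"clone_variability: {exc}{_find_line(path, 'clone_variability')}"
            ) from exc

    gen = _section(raw, "generate", path)
    fit = _section(raw, "fit", path)
    sens = _section(raw, "sensitivity", path)
    cv = _section(raw, "crossval", path)

    sampling = gen.get("sampling_times")
    if sampling is None:
        step = float(gen.get("sampling_interval", 0.5))
        sampling = np.arange(0.0, schedule.t_end + 1e-9, step)
    else:
        sampling = np.asarray(sampling, dtype=float)

    fit_bounds = fit.get("bounds")
    if fit_bounds is not None:
        fit_bounds = {k: (float(v[0]), float(v[1])) for k, v in fit_bounds.items()}

    return PipelineConfig(
        parameters=params,
        variants=variants,
        schedule=schedule,
        solver=solver,
        noise=noise,
        clone_variability=clone_var,
        stages=_section(raw, "stages", path) or {},
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
        sampling_times=sampling,
        n_clones=int(gen.get("n_clones", 4)),
        fit_free=list(fit.get("free", ["k_tx_R", "K_tetR", "k_agg"])),
        fit_bounds=fit_bounds,
        fit_n_starts=int(fit.get("n_starts", 20)),
        sensitivity_variant=sens.get("variant", "WT_STRONG"),
        sensitivity_perturbation=float(sens.get("perturbation", 0.05)),
        crossval_k=int(cv.get("k", 4)),
        crossval_unit=cv.get("unit", "clone"),
        crossval_n_starts=int(cv.get("n_starts", 4)),
    )
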