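"""Headline comparisons and the end-to-end pipeline.

``compare_variants`` condenses per-variant trajectories into the study's
headline numbers: end-point GFP, the 8-h soluble fractions and the percent
reduction of GFP relative to the no-feedback control (whose maximum over
the post-induction window is the circuit's headline figure of merit).
``run_pipeline`` wires generation, simulation, fitting, sensitivity
analysis, cross-validation and comparison together from a single config
file and writes deterministic CSV/JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import TimeCourseDataset, cross_validate, fit_parameters, local_sensitivity
from .config import ConfigError, PipelineConfig, load_config
from .dde import SolverSettings, Trajectory, simulate
from .model import CircuitError, CircuitParameters, observables
from .synth import (
    CloneVariabilityModel,
    NoiseModel,
    generate_fraction_measurements,
    generate_timecourse,
    merge_datasets,
    reference_total_gfp_at,
)

__all__ = ["ComparisonTable", "compare_variants", "run_pipeline", "PipelineError"]

REFERENCE_LABEL = "NO_FB"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ComparisonTable:
    """Per-variant end-point summaries and reductions vs the no-feedback control."""

    table: pd.DataFrame
    t_fraction: float
    flags: dict

    def max_reduction(self, variant: str, on: str = "total") -> float:
        col = {"total": "max_reduction_total_pct", "fluorescence": "max_reduction_fluor_pct"}[on]
        return float(self.table.set_index("variant").loc[variant, col])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_variants(
    trajectories: dict[str, Trajectory],
    t_fraction: float = 8.0,
    n_grid: int = 201,
) -> ComparisonTable:
    """Summarize a set of variant trajectories against the NO_FB control.

    The reduction of a variant v at time t is
    ``100 * (1 - gfp_v(t) / gfp_NO_FB(t))``, evaluated on a post-induction
    grid for both total GFP and the fluorescence observable; the table
    reports end-point values, soluble fractions at ``t_fraction`` (the 8-h
    fractionation time by default) and the maximum reduction with the time
    at which it occurs.  Times where the control's GFP is zero are flagged
    rather than divided through.
    """
    if REFERENCE_LABEL not in trajectories:
        raise CircuitError(f"comparison requires a {REFERENCE_LABEL} trajectory")
    ref = trajectories[REFERENCE_LABEL]
    scheds = {(tr.schedule.iptg_conc, tr.schedule.t_induce, tr.schedule.t_end)
              for tr in trajectories.values()}
    if len(scheds) > 1:
        raise CircuitError("all trajectories must share one induction schedule")
    sched = ref.schedule
    # strictly post-induction grid; at t_induce itself all variants coincide
    t0 = min(sched.t_induce + 0.05 * (sched.t_end - sched.t_induce), sched.t_end)
    grid = np.linspace(t0, sched.t_end, n_grid)

    ref_total = np.asarray(ref.observable("total_gfp", grid), dtype=float)
    ref_fluor = np.asarray(ref.observable("fluorescence_equiv", grid), dtype=float)
    flags: dict = {}
    ok_t = ref_total > 0
    ok_f = ref_fluor > 0
    if not ok_t.all() or not ok_f.all():
        flags["reference_zero"] = "control GFP is zero at some evaluation times; skipped"

    rows = []
    for label, tr in sorted(trajectories.items()):
        end = observables(tr.at(sched.t_end), tr.params)
        sf = float(tr.observable("soluble_fraction", min(t_fraction, sched.t_end)))
        tot = np.asarray(tr.observable("total_gfp", grid), dtype=float)
        flu = np.asarray(tr.observable("fluorescence_equiv", grid), dtype=float)
        red_t = 100.0 * (1.0 - tot[ok_t] / ref_total[ok_t])
        red_f = 100.0 * (1.0 - flu[ok_f] / ref_fluor[ok_f])
        i_t = int(np.argmax(red_t)) if red_t.size else 0
        rows.append(
            {
                "variant": label,
                "total_gfp_end": end["total_gfp"],
                "fluorescence_end": end["fluorescence_equiv"],
                "soluble_fraction_end": end["soluble_fraction"],
                f"soluble_fraction_{t_fraction:g}h": sf,
                "reduction_total_end_pct": float(red_t[-1]) if red_t.size else np.nan,
                "reduction_fluor_end_pct": float(red_f[-1]) if red_f.size else np.nan,
                "max_reduction_total_pct": float(np.max(red_t)) if red_t.size else np.nan,
                "t_max_reduction_h": float(grid[ok_t][i_t]) if red_t.size else np.nan,
                "max_reduction_fluor_pct": float(np.max(red_f)) if red_f.size else np.nan,
            }
        )
    return ComparisonTable(table=pd.DataFrame(rows), t_fraction=t_fraction, flags=flags)


def _config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_plots(outdir, trajs, table):  # pragma: no cover - optional artifact
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for label, tr in sorted(trajs.items()):
        grid = np.linspace(0, tr.schedule.t_end, 200)
        ax1.plot(grid, tr.observable("total_gfp", grid), label=label)
    ax1.set_xlabel("time (h)")
    ax1.set_ylabel("total GFP (conc. units)")
    ax1.legend(fontsize=8)
    tb = table.table
    ax2.bar(tb["variant"], tb[[c for c in tb.columns if c.startswith("soluble_fraction_") and c.endswith("h")][0]])
    ax2.set_ylabel("soluble fraction")
    ax2.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(Path(outdir) / "comparison.png", dpi=120)
    plt.close(fig)


def run_pipeline(
    config_path,
    seed: int | None = None,
    out_dir=None,
    no_plots: bool = False,
) -> Path:
    """Execute the configured stages end to end; return the artifact directory.

    Stages (each optional in the config): ``generate`` synthetic datasets,
    ``simulate`` all variants, ``fit``, ``sensitivity``, ``crossval`` and
    ``compare``.  Outputs are tidy CSVs and JSON reports plus a
    ``run_log.json`` recording the seed, config hash and package version;
    rerunning with the same config and seed reproduces the CSVs byte for
    byte.
    """
    cfg: PipelineConfig = load_config(config_path)
    seed = cfg.seed if seed is None else seed
    outdir = Path(out_dir or cfg.out_dir or "stresscircuit_out")
    outdir.mkdir(parents=True, exist_ok=True)

    params = cfg.parameters
    schedule = cfg.schedule
    variants = cfg.variants
    settings = cfg.solver
    stage = "setup"
    log = {
        "seed": seed,
        "config": str(config_path),
        "config_sha256": _config_hash(config_path),
        "version": __version__,
        "stages": [],
    }

    try:
        trajs = None
        if cfg.stages.get("simulate", True) or cfg.stages.get("compare", True):
            stage = "simulate"
            trajs = {label: simulate(params, v, schedule, settings) for label, v in variants.items()}
            frames = [tr.to_frame(run_id=f"seed{seed}") for tr in trajs.values()]
            pd.concat(frames, ignore_index=True).to_csv(outdir / "trajectories.csv", index=False)
            pd.concat(
                [tr.events_frame().assign(variant=label) for label, tr in trajs.items()],
                ignore_index=True,
            ).to_csv(outdir / "events.csv", index=False)
            log["stages"].append("simulate")

        dataset = None
        if cfg.stages.get("generate", True):
            stage = "generate"
            noise = cfg.noise or NoiseModel()
            clone_var = cfg.clone_variability or CloneVariabilityModel()
            ref_total = None
            if REFERENCE_LABEL in variants:
                ref_total = reference_total_gfp_at(params, 8.0, schedule, settings)
            per_variant = {}
            for i, (label, v) in enumerate(sorted(variants.items())):
                ds = generate_timecourse(
                    params, v, schedule, cfg.sampling_times, cfg.n_clones,
                    noise, clone_var, seed + 1000 + i, settings,
                )
                if ref_total is not None:
                    fr = generate_fraction_measurements(
                        params, v, 8.0, cfg.n_clones, noise, clone_var,
                        seed + 2000 + i, schedule,
                        reference_total_gfp=None if label == REFERENCE_LABEL else ref_total,
                        settings=settings,
                    )
                    ds.fractions = fr
                per_variant[label] = ds
            dataset = merge_datasets(per_variant)
            dataset.to_csv(outdir / "dataset.csv", outdir / "fractions.csv")
            log["stages"].append("generate")

        if cfg.stages.get("fit", False):
            stage = "fit"
            if dataset is None:
                raise PipelineError("fit stage requires the generate stage (no dataset)")
            fit = fit_parameters(
                dataset, params, cfg.fit_free, cfg.fit_bounds, schedule, variants,
                settings, seed=seed, n_starts=cfg.fit_n_starts,
            )
            fit.to_json(outdir / "fit.json")
            log["stages"].append("fit")

        if cfg.stages.get("sensitivity", False):
            stage = "sensitivity"
            label = cfg.sensitivity_variant
            if label not in variants:
                raise PipelineError(f"sensitivity stage: unknown variant {label!r}")
            rep = local_sensitivity(
                params, variants[label], schedule,
                perturbation=cfg.sensitivity_perturbation, settings=settings,
            )
            rep.to_json(outdir / "sensitivity.json")
            rep.coefficients.rename_axis("parameter").to_csv(outdir / "sensitivity.csv")
            log["stages"].append("sensitivity")

        if cfg.stages.get("crossval", False):
            stage = "crossval"
            if dataset is None:
                raise PipelineError("crossval stage requires the generate stage (no dataset)")
            cv = cross_validate(
                dataset, cfg.fit_free, k=cfg.crossval_k, unit=cfg.crossval_unit,
                seed=seed, init=params, bounds=cfg.fit_bounds, schedule=schedule,
                variants=variants, settings=settings, n_starts=cfg.crossval_n_starts,
            )
            cv.to_json(outdir / "crossval.json")
            log["stages"].append("crossval")

        if cfg.stages.get("compare", True):
            stage = "compare"
            if REFERENCE_LABEL not in variants:
                raise PipelineError(
                    f"compare stage requires a {REFERENCE_LABEL} variant in the config"
                )
            table = compare_variants(trajs)
            table.to_csv(outdir / "comparison.csv")
            if not no_plots:
                _write_plots(outdir, trajs, table)
            log["stages"].append("compare")
    except (PipelineError, ConfigError):
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
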