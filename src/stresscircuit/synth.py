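"""Synthetic plate-reader and fractionation data with known ground truth.

Emulates the study conditions of a batch-culture characterization: cultures
inoculated at OD600 0.1 grow exponentially at each clone's specific growth
rate, are induced with 1 mM IPTG at 2 h, and are sampled at regular
intervals over 12 h for OD and GFP fluorescence per OD (four biological
replicates per construct).  Soluble/insoluble GFP fractionation is sampled
at 8 h.  Clone-to-clone variability enters as lognormal multipliers on the
feedback promoter strength, feedback RBS strength and growth rate;
measurement noise is multiplicative lognormal on fluorescence and OD and
additive truncated-Gaussian on fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibrate import TimeCourseDataset
from .dde import SolverSettings, simulate
from .model import (
    STANDARD_VARIANTS,
    CircuitError,
    CircuitParameters,
    FeedbackVariant,
    InductionSchedule,
)

__all__ = [
    "NoiseModel",
    "CloneVariabilityModel",
    "generate_timecourse",
    "generate_fraction_measurements",
    "generate_characterization_suite",
    "reference_total_gfp_at",
    "merge_datasets",
]

OD_INOCULUM = 0.1  # starting optical density of every culture
OD_CEILING = 4.0  # stationary-phase cap on the synthetic OD trace


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes.

    ``fluor_cv`` / ``od_cv`` are coefficients of variation of mean-one
    multiplicative lognormal noise; ``fraction_sd`` is the additive standard
    deviation applied to soluble fractions (results truncated to [0, 1]).
    """

    fluor_cv: float = 0.1
    od_cv: float = 0.05
    fraction_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.fluor_cv, self.od_cv, self.fraction_sd) < 0:
            raise CircuitError("noise magnitudes must be nonnegative")

    def lognormal_factor(self, cv: float, rng: np.random.Generator, size=None):
        """Mean-one lognormal multiplier(s) with coefficient of variation cv."""
        if cv == 0:
            return np.ones(size) if size is not None else 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class CloneVariabilityModel:
    """Biological clone-to-clone variability.

    Each clone draws lognormal multipliers (median 1) on the feedback
    promoter scale, the feedback RBS scale and the growth rate, reflecting
    clone-specific differences in cell state and growth.  ``seed``
    optionally pins the clone draws independently of the measurement-noise
    stream.
    """

    sigma_promoter: float = 0.2
    sigma_rbs: float = 0.2
    sigma_mu: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.sigma_promoter, self.sigma_rbs, self.sigma_mu) < 0:
            raise CircuitError("variability sigmas must be nonnegative")

    def draw(self, n_clones: int, rng: np.random.Generator) -> pd.DataFrame:
        r = np.random.default_rng(self.seed) if self.seed is not None else rng
        return pd.DataFrame(
            {
                "promoter_mult": r.lognormal(0.0, self.sigma_promoter, n_clones),
                "rbs_mult": r.lognormal(0.0, self.sigma_rbs, n_clones),
                "mu_mult": r.lognormal(0.0, self.sigma_mu, n_clones),
            }
        )


def _clone_trajectory(params, variant, schedule, mult, settings):
    v = FeedbackVariant(
        variant.label,
        promoter_scale=variant.promoter_scale * mult["promoter_mult"],
        rbs_scale=variant.rbs_scale * mult["rbs_mult"],
    )
    p = params.with_updates(mu0=params.mu0 * mult["mu_mult"])
    return simulate(p, v, schedule, settings), p


def _od_trace(times, mu, t_induce):
    # exponential growth at the clone's rate, capped at stationary phase
    return np.minimum(OD_INOCULUM * np.exp(mu * np.asarray(times, dtype=float)), OD_CEILING)


def generate_timecourse(
    true_params: CircuitParameters,
    variant: FeedbackVariant,
    schedule: InductionSchedule,
    sampling_times,
    n_clones: int = 4,
    noise: NoiseModel = NoiseModel(),
    clone_var: CloneVariabilityModel = CloneVariabilityModel(),
    seed: int = 0,
    settings: SolverSettings = SolverSettings(),
    clone_prefix: str | None = None,
) -> TimeCourseDataset:
    """Simulate noisy replicate growth/fluorescence measurements.

    Each of ``n_clones`` biological replicates draws its variability
    multipliers, is simulated forward, and is observed at
    ``sampling_times``: OD600 from exponential growth at the clone's rate
    and GFP fluorescence per OD from the native-GFP observable, both with
    multiplicative measurement noise.  Fully reproducible from ``seed``.
    """
    sampling_times = np.asarray(sampling_times, dtype=float)
    if sampling_times.min() < 0 or sampling_times.max() > schedule.t_end:
        raise CircuitError("sampling times must lie within [0, t_end]")
    if n_clones < 1:
        raise CircuitError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    mults = clone_var.draw(n_clones, rng)
    prefix = clone_prefix or f"{variant.label}_c"

    rows = []
    traj_cache: dict = {}
    for c in range(n_clones):
        mult = mults.iloc[c]
        key = (round(mult["promoter_mult"], 15), round(mult["rbs_mult"], 15), round(mult["mu_mult"], 15))
        if key not in traj_cache:  # identical multipliers -> identical clone dynamics
            traj_cache[key] = _clone_trajectory(true_params, variant, schedule, mult, settings)
        traj, p_c = traj_cache[key]
        fluor = traj.observable("fluorescence_equiv", sampling_times)
        od = _od_trace(sampling_times, p_c.mu0, schedule.t_induce)
        f_noise = noise.lognormal_factor(noise.fluor_cv, rng, size=len(sampling_times))
        od_noise = noise.lognormal_factor(noise.od_cv, rng, size=len(sampling_times))
        rows.append(
            pd.DataFrame(
                {
                    "time_h": sampling_times,
                    "clone_id": f"{prefix}{c + 1}",
                    "variant": variant.label,
                    "od600": od * od_noise,
                    "fluorescence_per_od": np.asarray(fluor) * f_noise,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    meta = {
        "n_replicates": n_clones,
        "medium": "M9-glucose-like",
        "seed": seed,
        "true_variant": {
            "label": variant.label,
            "promoter_scale": variant.promoter_scale,
            "rbs_scale": variant.rbs_scale,
        },
    }
    return TimeCourseDataset(records=records, fractions=None, metadata=meta)


def generate_fraction_measurements(
    true_params: CircuitParameters,
    variant: FeedbackVariant,
    t_sample: float = 8.0,
    n_clones: int = 4,
    noise: NoiseModel = NoiseModel(),
    clone_var: CloneVariabilityModel = CloneVariabilityModel(),
    seed: int = 0,
    schedule: InductionSchedule = InductionSchedule(),
    reference_total_gfp: float | None = None,
    settings: SolverSettings = SolverSettings(),
    clone_prefix: str | None = None,
) -> pd.DataFrame:
    """End-point soluble/insoluble fractionation table for one construct.

    Per clone: the soluble GFP fraction at ``t_sample`` (additive noise,
    truncated to [0, 1]) and the total GFP relative to a no-feedback
    reference (the construct without the feedback plasmid is the internal
    reference with GFP content 1).  For a non-``NO_FB`` variant the
    reference total must be supplied via ``reference_total_gfp`` (see
    :func:`reference_total_gfp_at`).
    """
    if t_sample > schedule.t_end:
        raise CircuitError("t_sample must not exceed the schedule horizon")
    if reference_total_gfp is None:
        if variant.label != "NO_FB":
            raise CircuitError(
                "relative total GFP requires a NO_FB reference: pass reference_total_gfp"
            )
    rng = np.random.default_rng(seed)
    mults = clone_var.draw(n_clones, rng)
    prefix = clone_prefix or f"{variant.label}_c"

    rows = []
    totals = []
    fracs = []
    traj_cache: dict = {}
    for c in range(n_clones):
        mult = mults.iloc[c]
        key = (round(mult["promoter_mult"], 15), round(mult["rbs_mult"], 15), round(mult["mu_mult"], 15))
        if key not in traj_cache:
            traj_cache[key] = _clone_trajectory(true_params, variant, schedule, mult, settings)
        traj, _ = traj_cache[key]
        totals.append(float(traj.observable("total_gfp", t_sample)))
        fracs.append(float(traj.observable("soluble_fraction", t_sample)))
    if reference_total_gfp is None:
        # designated reference clone: first NO_FB clone
        reference_total_gfp = totals[0]
    for c in range(n_clones):
        frac_obs = fracs[c]
        if noise.fraction_sd > 0:
            frac_obs += rng.normal(0.0, noise.fraction_sd)
        frac_obs = min(max(frac_obs, 0.0), 1.0)
        total_rel = totals[c] / reference_total_gfp
        total_rel *= float(noise.lognormal_factor(noise.fluor_cv, rng))
        rows.append(
            {
                "clone_id": f"{prefix}{c + 1}",
                "variant": variant.label,
                "time_h": t_sample,
                "soluble_fraction": frac_obs,
                "total_gfp_relative": total_rel,
            }
        )
    return pd.DataFrame(rows)


def reference_total_gfp_at(
    params: CircuitParameters,
    t_sample: float = 8.0,
    schedule: InductionSchedule = InductionSchedule(),
    settings: SolverSettings = SolverSettings(),
) -> float:
    """Noise-free NO_FB total GFP at ``t_sample`` (fractionation reference)."""
    traj = simulate(params, STANDARD_VARIANTS["NO_FB"], schedule, settings)
    return float(traj.observable("total_gfp", t_sample))


def generate_characterization_suite(
    seed: int = 0,
    params: CircuitParameters = CircuitParameters(),
    noise: NoiseModel = NoiseModel(),
    clone_var: CloneVariabilityModel = CloneVariabilityModel(),
    settings: SolverSettings = SolverSettings(),
) -> dict[str, TimeCourseDataset]:
    """The canonical four-construct characterization bundle.

    One dataset per expression setup (NO_FB, WT_STRONG, MUT_STRONG,
    MUT_WEAK): 4 clones each, sampled every 0.5 h over 0-12 h with 1 mM
    IPTG induction at 2 h, plus an 8-h fractionation table with totals
    relative to the no-feedback construct.  The underlying parameter set is
    the package's canonical calibrated fixture, for which end-point GFP is
    ordered NO_FB > MUT_WEAK > MUT_STRONG > WT_STRONG.
    """
    schedule = InductionSchedule(iptg_conc=1.0, t_induce=2.0, t_end=12.0)
    sampling = np.arange(0.0, 12.0 + 1e-9, 0.5)
    ref_total = reference_total_gfp_at(params, 8.0, schedule, settings)
    out: dict[str, TimeCourseDataset] = {}
    ss = np.random.SeedSequence(seed)
    for sub, (label, variant) in zip(ss.spawn(len(STANDARD_VARIANTS)), STANDARD_VARIANTS.items()):
        s1, s2 = sub.generate_state(2) % np.uint64(2**31)
        ds = generate_timecourse(
            params, variant, schedule, sampling, 4, noise, clone_var, int(s1), settings
        )
        frac = generate_fraction_measurements(
            params,
            variant,
            8.0,
            4,
            noise,
            clone_var,
            int(s2),
            schedule,
            reference_total_gfp=None if label == "NO_FB" else ref_total,
            settings=settings,
        )
        out[label] = replace(ds, fractions=frac)
    return out


def merge_datasets(datasets: dict[str, TimeCourseDataset]) -> TimeCourseDataset:
    """Concatenate per-variant datasets into one multi-variant dataset."""
    records = pd.concat([d.records for d in datasets.values()], ignore_index=True)
    fracs = [d.fractions for d in datasets.values() if d.fractions is not None]
    fractions = pd.concat(fracs, ignore_index=True) if fracs else None
    meta = {"n_replicates": next(iter(datasets.values())).metadata.get("n_replicates")}
    return TimeCourseDataset(records=records, fractions=fractions, metadata=meta)
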