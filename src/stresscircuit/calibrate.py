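"""Calibration of the circuit model against fluorescence time courses.

Covers the unit conversion between plate-reader fluorescence and model
concentration, weighted least-squares parameter estimation on replicate
time courses (with optional end-point soluble-fraction terms), local
sensitivity analysis by central differences, and grouped cross-validation
for the generalization error of the fitted model.

Fluorescence residuals are taken on the log scale (measurement noise is
multiplicative); soluble-fraction residuals stay linear and are weighted so
both data kinds contribute comparably.  Positive free parameters are
optimized in log10 space with Latin-hypercube multi-start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dde import SolverSettings, Trajectory, simulate
from .model import (
    STANDARD_VARIANTS,
    CircuitError,
    CircuitParameters,
    FeedbackVariant,
    InductionSchedule,
)

__all__ = [
    "TimeCourseDataset",
    "FitResult",
    "SensitivityReport",
    "CrossValidationReport",
    "IdentifiabilityWarning",
    "fluorescence_to_molarity",
    "fit_parameters",
    "local_sensitivity",
    "cross_validate",
]

RECORD_COLUMNS = ("time_h", "clone_id", "variant", "od600", "fluorescence_per_od")
FRACTION_COLUMNS = ("clone_id", "variant", "time_h", "soluble_fraction", "total_gfp_relative")

#: Solver settings used inside iterative fitting (slightly relaxed for speed).
FIT_SOLVER = SolverSettings(rel_tol=1e-6, abs_tol=1e-8)


class IdentifiabilityWarning(UserWarning):
    """The requested free parameters exceed what the data can constrain."""


@dataclass
class TimeCourseDataset:
    """Replicate-tagged growth/fluorescence measurements.

    ``records`` is a tidy table with columns ``time_h, clone_id, variant,
    od600, fluorescence_per_od`` (hours, linear fluorescence per OD600);
    ``fractions`` optionally holds end-point fractionation rows
    ``clone_id, variant, time_h, soluble_fraction, total_gfp_relative``.
    """

    records: pd.DataFrame
    fractions: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise CircuitError(f"records missing column(s): {sorted(missing)}")
        if len(self.records) == 0:
            raise CircuitError("dataset has no records")
        if (self.records["time_h"] < 0).any():
            raise CircuitError("record times must be nonnegative")
        if (self.records["fluorescence_per_od"] < 0).any():
            raise CircuitError("fluorescence_per_od must be nonnegative")
        if self.records["variant"].nunique() < 1:
            raise CircuitError("at least one variant must be present")
        if self.fractions is not None:
            fmissing = set(FRACTION_COLUMNS) - set(self.fractions.columns)
            if fmissing:
                raise CircuitError(f"fractions missing column(s): {sorted(fmissing)}")
            sf = self.fractions["soluble_fraction"]
            if ((sf < 0) | (sf > 1)).any():
                raise CircuitError("soluble_fraction must lie in [0, 1]")

    @property
    def variants(self) -> list:
        return sorted(self.records["variant"].unique())

    @property
    def clones(self) -> list:
        return sorted(self.records["clone_id"].unique())

    def subset_units(self, unit: str, keep) -> "TimeCourseDataset":
        """Restrict to the given clones or variants (for cross-validation)."""
        col = {"clone": "clone_id", "variant": "variant"}[unit]
        keep = set(keep)
        rec = self.records[self.records[col].isin(keep)].reset_index(drop=True)
        fr = None
        if self.fractions is not None:
            fr = self.fractions[self.fractions[col].isin(keep)].reset_index(drop=True)
            if len(fr) == 0:
                fr = None
        return TimeCourseDataset(records=rec, fractions=fr, metadata=dict(self.metadata))

    def to_csv(self, path, fractions_path=None) -> None:
        self.records.to_csv(path, index=False)
        if self.fractions is not None and fractions_path is not None:
            self.fractions.to_csv(fractions_path, index=False)

    @classmethod
    def from_csv(cls, path, fractions_path=None, metadata: dict | None = None):
        records = pd.read_csv(path)
        fractions = pd.read_csv(fractions_path) if fractions_path else None
        return cls(records=records, fractions=fractions, metadata=metadata or {})


@dataclass
class FitResult:
    """Outcome of a parameter fit."""

    params: CircuitParameters
    free: list
    objective: float
    residuals: dict  # variant -> DataFrame(time_h, clone_id, residual)
    success: bool
    bounds: dict
    seed: int
    n_starts: int
    n_evaluations: int
    message: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "free": list(self.free),
            "objective": self.objective,
            "success": self.success,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "n_starts": self.n_starts,
            "n_evaluations": self.n_evaluations,
            "message": self.message,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class SensitivityReport:
    """Normalized local sensitivities S = d ln(output) / d ln(parameter)."""

    coefficients: pd.DataFrame  # index: parameter, columns: outputs
    ranking: list
    perturbation: float
    flags: dict = field(default_factory=dict)

    def top(self, n: int = 2) -> list:
        return self.ranking[:n]

    def to_json(self, path=None) -> str:
        payload = {
            "perturbation": self.perturbation,
            "ranking": list(self.ranking),
            "coefficients": {
                p: {c: float(self.coefficients.loc[p, c]) for c in self.coefficients.columns}
                for p in self.coefficients.index
            },
            "flags": self.flags,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class CrossValidationReport:
    """Grouped k-fold generalization assessment."""

    folds: list  # list of held-out unit lists
    train_errors: np.ndarray  # mean squared residual per fold (training)
    test_errors: np.ndarray  # same, held-out
    unit: str
    summary: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "unit": self.unit,
            "folds": [list(f) for f in self.folds],
            "train_errors": [float(x) for x in self.train_errors],
            "test_errors": [float(x) for x in self.test_errors],
            "summary": self.summary,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def fluorescence_to_molarity(fluor_per_od, c_fluor: float):
    """Convert normalized fluorescence to model concentration units.

    Linear map ``value * c_fluor``; the exact inverse of the model's
    ``fluorescence_equiv`` observable.
    """
    if c_fluor <= 0:
        raise CircuitError(f"c_fluor must be positive, got {c_fluor}")
    arr = np.asarray(fluor_per_od, dtype=float)
    if np.any(arr < 0):
        raise CircuitError("fluorescence must be nonnegative")
    out = arr * c_fluor
    return float(out) if np.ndim(fluor_per_od) == 0 else out


def _simulate_variants(params, labels, variants, schedule, settings):
    trajs = {}
    for label in labels:
        if label not in variants:
            raise CircuitError(f"dataset variant {label!r} has no FeedbackVariant mapping")
        trajs[label] = simulate(params, variants[label], schedule, settings)
    return trajs


def _residual_vector(params, data, variants, schedule, settings, log_floor):
    """Stacked residuals: log-fluorescence terms then weighted fraction terms."""
    labels = data.variants
    trajs = _simulate_variants(params, labels, variants, schedule, settings)
    res = []
    tagged = {}
    for label in labels:
        sub = data.records[data.records["variant"] == label]
        pred = np.asarray(trajs[label].observable("fluorescence_equiv", sub["time_h"].to_numpy()))
        obs = sub["fluorescence_per_od"].to_numpy()
        r = np.log(obs + log_floor) - np.log(pred + log_floor)
        res.append(r)
        tagged[label] = pd.DataFrame(
            {"time_h": sub["time_h"].to_numpy(), "clone_id": sub["clone_id"].to_numpy(), "residual": r}
        )
    if data.fractions is not None and len(data.fractions) > 0:
        w = np.sqrt(len(data.records) / len(data.fractions))
        fr = []
        for label in sorted(data.fractions["variant"].unique()):
            sub = data.fractions[data.fractions["variant"] == label]
            traj = trajs.get(label)
            if traj is None:
                traj = simulate(params, variants[label], schedule, settings)
            pred_sf = np.asarray(traj.observable("soluble_fraction", sub["time_h"].to_numpy()))
            fr.append(w * (sub["soluble_fraction"].to_numpy() - pred_sf))
        res.append(np.concatenate(fr))
    return np.concatenate(res), tagged


def _log_floor(data) -> float:
    # fixed small offset keeps log residuals finite near zero fluorescence;
    # scales with the dataset so the objective is unit-free and
    # record-order invariant
    top = float(data.records["fluorescence_per_od"].max())
    return max(1e-6 * top, 1e-12)


def _check_identifiability(data, free):
    coords = set(
        zip(data.records["variant"], np.round(data.records["time_h"].to_numpy(), 9))
    )
    n_info = len(coords)
    if data.fractions is not None:
        n_info += len(set(zip(data.fractions["variant"], np.round(data.fractions["time_h"], 9))))
    if n_info < len(free):
        warnings.warn(
            f"{len(free)} free parameters but only {n_info} distinct measurement "
            f"coordinates; the fit is underdetermined",
            IdentifiabilityWarning,
            stacklevel=3,
        )


def fit_parameters(
    data: TimeCourseDataset,
    init: CircuitParameters,
    free,
    bounds: dict | None = None,
    schedule: InductionSchedule = InductionSchedule(),
    variants: dict | None = None,
    settings: SolverSettings = FIT_SOLVER,
    seed: int = 0,
    n_starts: int = 20,
) -> FitResult:
    """Estimate the named free parameters from a time-course dataset.

    Minimizes the sum of squared log-residuals between the model's
    fluorescence observable and the observed fluorescence-per-OD (all
    variants, clones and times), plus weighted linear residuals on any
    end-point soluble fractions.  Optimization runs ``n_starts`` local
    TRF solves (first start at ``init``, the rest Latin-hypercube over the
    bounds, reproducible from ``seed``) in log10 parameter space and keeps
    the best.

    ``bounds`` maps parameter name to a positive (lo, hi) pair; the default
    spans two decades around ``init``.
    """
    free = list(free)
    names = set(CircuitParameters.parameter_names())
    unknown = set(free) - names
    if unknown:
        raise CircuitError(f"unknown free parameter(s): {sorted(unknown)}")
    variants = variants or STANDARD_VARIANTS
    for label in data.variants:
        if label not in variants:
            raise CircuitError(f"dataset variant {label!r} has no FeedbackVariant mapping")
    _check_identifiability(data, free)

    bounds = dict(bounds or {})
    lo = np.empty(len(free))
    hi = np.empty(len(free))
    for i, name in enumerate(free):
        v0 = getattr(init, name)
        if name in bounds:
            lo[i], hi[i] = bounds[name]
        else:
            if v0 <= 0:
                raise CircuitError(
                    f"free parameter {name} has nonpositive initial value; "
                    "explicit positive bounds are required"
                )
            lo[i], hi[i] = v0 / 10.0, v0 * 10.0
            bounds[name] = (lo[i], hi[i])
        if lo[i] <= 0 or hi[i] <= lo[i]:
            raise CircuitError(f"bounds for {name} must be positive with hi > lo")

    log_lo, log_hi = np.log10(lo), np.log10(hi)
    floor = _log_floor(data)
    n_eval = 0

    def resid(x):
        nonlocal n_eval
        n_eval += 1
        theta = {name: 10.0**xi for name, xi in zip(free, x)}
        try:
            r, _ = _residual_vector(
                init.with_updates(**theta), data, variants, schedule, settings, floor
            )
        except Exception:
            return np.full(_n_resid, 1e6)
        return r

    _n_resid = len(_residual_vector(init, data, variants, schedule, settings, floor)[0])

    x_init = np.clip(np.log10([getattr(init, n) for n in free]), log_lo, log_hi)
    starts = [x_init]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        pts = sampler.random(n_starts - 1)
        starts.extend(log_lo + pts * (log_hi - log_lo))

    best = None
    failures = []
    for x0 in starts:
        try:
            # diff_step ~ 2% in log10 space keeps the numerical jacobian well
            # above the integrator's error floor
            sol = least_squares(
                resid, x0, bounds=(log_lo, log_hi), method="trf",
                xtol=1e-9, ftol=1e-9, diff_step=0.02,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise CircuitError(f"all {len(starts)} optimization starts failed: {failures[:3]}")

    theta = {name: 10.0**xi for name, xi in zip(free, best.x)}
    p_hat = init.with_updates(**theta)
    r, tagged = _residual_vector(p_hat, data, variants, schedule, settings, floor)

    jac = np.asarray(best.jac)
    if jac.size and np.linalg.matrix_rank(jac, tol=1e-8 * max(1.0, np.abs(jac).max())) < len(free):
        warnings.warn(
            "Jacobian at the optimum is rank deficient; some free parameters "
            "are not identifiable from this dataset",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    return FitResult(
        params=p_hat,
        free=free,
        objective=float(np.sum(r**2)),
        residuals=tagged,
        success=bool(best.success),
        bounds=bounds,
        seed=seed,
        n_starts=len(starts),
        n_evaluations=n_eval,
        message=str(best.message),
    )


def _endpoint_outputs(params, variant, schedule, outputs, t_eval, settings):
    traj = simulate(params, variant, schedule, settings)
    t = schedule.t_end if t_eval is None else t_eval
    from .model import observables

    obs = observables(traj.at(float(t)), traj.params)
    return np.array([obs[name] for name in outputs])


def local_sensitivity(
    params: CircuitParameters,
    variant: FeedbackVariant,
    schedule: InductionSchedule = InductionSchedule(),
    outputs=("total_gfp", "soluble_fraction"),
    perturbation: float = 0.05,
    t_eval: float | None = None,
    parameters=None,
    settings: SolverSettings = FIT_SOLVER,
) -> SensitivityReport:
    """Normalized local sensitivity of end-point outputs to each parameter.

    For parameter theta and output y the coefficient is the logarithmic
    central difference ``S = Δln y / Δln theta`` over ``theta*(1 ± h)``
    (exact for power-law dependence, e.g. S = -1 for ``c_fluor`` against
    the fluorescence observable).  Zero-valued outputs fall back to an
    absolute-scale difference and are flagged; zero-valued parameters get
    S = 0 with a flag.  Parameters are ranked by mean |S| over outputs.
    """
    if not 0 < perturbation <= 0.5:
        raise CircuitError("perturbation must lie in (0, 0.5]")
    outputs = list(outputs)
    pnames = list(parameters) if parameters is not None else list(CircuitParameters.parameter_names())
    f0 = _endpoint_outputs(params, variant, schedule, outputs, t_eval, settings)

    coef = pd.DataFrame(0.0, index=pnames, columns=outputs)
    flags: dict = {}
    for name in pnames:
        v = getattr(params, name)
        if v == 0:
            flags[name] = "zero_parameter"
            continue
        fp = _endpoint_outputs(
            params.with_updates(**{name: v * (1 + perturbation)}),
            variant, schedule, outputs, t_eval, settings,
        )
        fm = _endpoint_outputs(
            params.with_updates(**{name: v * (1 - perturbation)}),
            variant, schedule, outputs, t_eval, settings,
        )
        dln_theta = np.log1p(perturbation) - np.log1p(-perturbation)
        for j, out in enumerate(outputs):
            if fp[j] == fm[j]:
                coef.loc[name, out] = 0.0
            elif f0[j] == 0 or fp[j] <= 0 or fm[j] <= 0:
                coef.loc[name, out] = (fp[j] - fm[j]) / (2 * perturbation)
                flags[f"{name}:{out}"] = "absolute_scale"
            else:
                coef.loc[name, out] = (np.log(fp[j]) - np.log(fm[j])) / dln_theta

    agg = coef.abs().mean(axis=1)
    ranking = list(agg.sort_values(ascending=False, kind="stable").index)
    return SensitivityReport(
        coefficients=coef, ranking=ranking, perturbation=perturbation, flags=flags
    )


def cross_validate(
    data: TimeCourseDataset,
    free,
    k: int = 4,
    unit: str = "clone",
    seed: int = 0,
    init: CircuitParameters = CircuitParameters(),
    bounds: dict | None = None,
    schedule: InductionSchedule = InductionSchedule(),
    variants: dict | None = None,
    settings: SolverSettings = FIT_SOLVER,
    n_starts: int = 4,
) -> CrossValidationReport:
    """Grouped k-fold cross-validation of the fitted model.

    Units (biological clones by default, or whole variants) are shuffled
    with ``seed`` and partitioned into ``k`` folds; each fold is held out,
    the free parameters are refitted on the remainder, and the mean squared
    residual is evaluated on both splits.  The summary reports mean and
    standard deviation of the test error and the test/train ratio.
    """
    if unit not in ("clone", "variant"):
        raise CircuitError("unit must be 'clone' or 'variant'")
    if k < 2:
        raise CircuitError("k must be >= 2")
    variants = variants or STANDARD_VARIANTS
    col = {"clone": "clone_id", "variant": "variant"}[unit]
    units = sorted(data.records[col].unique())
    if k > len(units):
        raise CircuitError(f"k={k} exceeds the number of {unit} units ({len(units)})")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(units))
    folds = [sorted(order[i::k]) for i in range(k)]
    floor = _log_floor(data)

    train_err = np.empty(k)
    test_err = np.empty(k)
    for i, held in enumerate(folds):
        train = data.subset_units(unit, [u for u in units if u not in held])
        test = data.subset_units(unit, held)
        fit = fit_parameters(
            train, init, free, bounds, schedule, variants, settings,
            seed=seed + i, n_starts=n_starts,
        )
        r_tr, _ = _residual_vector(fit.params, train, variants, schedule, settings, floor)
        r_te, _ = _residual_vector(fit.params, test, variants, schedule, settings, floor)
        train_err[i] = float(np.mean(r_tr**2))
        test_err[i] = float(np.mean(r_te**2))

    mean_train = float(np.mean(train_err))
    mean_test = float(np.mean(test_err))
    summary = {
        "mean_train_error": mean_train,
        "mean_test_error": mean_test,
        "sd_test_error": float(np.std(test_err)),
        "test_train_ratio": mean_test / mean_train if mean_train > 0 else float("nan"),
    }
    return CrossValidationReport(
        folds=folds, train_errors=train_err, test_errors=test_err, unit=unit, summary=summary
    )
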