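"""Calibration tests: unit conversion, fitting, sensitivity, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from stresscircuit import CircuitParameters, InductionSchedule, STANDARD_VARIANTS
from stresscircuit.calibrate import (
    FIT_SOLVER,
    CircuitError,
    IdentifiabilityWarning,
    TimeCourseDataset,
    _log_floor,
    _residual_vector,
    cross_validate,
    fit_parameters,
    fluorescence_to_molarity,
    local_sensitivity,
)
from stresscircuit.synth import CloneVariabilityModel, NoiseModel, generate_timecourse

NO_NOISE = NoiseModel(0.0, 0.0, 0.0)
NO_VAR = CloneVariabilityModel(0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def clean_dataset(params, schedule):
    """Noiseless 2-clone WT_STRONG dataset on an hourly grid."""
    return generate_timecourse(
        params, STANDARD_VARIANTS["WT_STRONG"], schedule, np.arange(0.0, 12.5, 1.0),
        n_clones=2, noise=NO_NOISE, clone_var=NO_VAR, seed=7,
    )


class TestFluorescenceConversion:
    def test_zero_maps_to_zero(self):
        assert fluorescence_to_molarity(0.0, 50.0) == 0.0

    def test_unit_factor_is_identity(self):
        x = np.array([0.0, 1.5, 7.2])
        assert fluorescence_to_molarity(x, 1.0) == pytest.approx(x)

    def test_roundtrip_exact(self, params):
        m = 321.0
        fluor = m / params.c_fluor
        assert fluorescence_to_molarity(fluor, params.c_fluor) == pytest.approx(m, rel=1e-15)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(CircuitError):
            fluorescence_to_molarity(1.0, 0.0)


class TestDatasetValidation:
    def test_missing_column_rejected(self):
        with pytest.raises(CircuitError, match="missing column"):
            TimeCourseDataset(records=pd.DataFrame({"time_h": [1.0]}))

    def test_fraction_bounds_enforced(self, clean_dataset):
        bad = pd.DataFrame(
            {
                "clone_id": ["c1"], "variant": ["WT_STRONG"], "time_h": [8.0],
                "soluble_fraction": [1.2], "total_gfp_relative": [0.5],
            }
        )
        with pytest.raises(CircuitError, match="soluble_fraction"):
            TimeCourseDataset(records=clean_dataset.records, fractions=bad)

    def test_csv_roundtrip(self, clean_dataset, tmp_path):
        p = tmp_path / "records.csv"
        clean_dataset.to_csv(p)
        back = TimeCourseDataset.from_csv(p)
        pd.testing.assert_frame_equal(back.records, clean_dataset.records)


class TestFitParameters:
    def test_objective_zero_at_truth(self, clean_dataset, params, schedule):
        res = fit_parameters(
            clean_dataset, params, ["k_tx_R", "K_tetR", "k_agg"],
            schedule=schedule, seed=0, n_starts=1,
        )
        assert res.objective < 1e-8
        for name in res.free:
            assert getattr(res.params, name) == pytest.approx(getattr(params, name), rel=1e-3)

    def test_noiseless_recovery_within_5pct(self, clean_dataset, params, schedule):
        init = params.with_updates(
            k_tx_R=params.k_tx_R * 1.4, K_tetR=params.K_tetR * 0.7, k_agg=params.k_agg * 1.3
        )
        res = fit_parameters(
            clean_dataset, init, ["k_tx_R", "K_tetR", "k_agg"],
            schedule=schedule, seed=1, n_starts=1,
        )
        for name in res.free:
            assert getattr(res.params, name) == pytest.approx(getattr(params, name), rel=0.05)

    def test_single_timepoint_triggers_identifiability_warning(self, params, schedule):
        ds = generate_timecourse(
            params, STANDARD_VARIANTS["WT_STRONG"], schedule, [8.0],
            n_clones=4, noise=NO_NOISE, clone_var=NO_VAR, seed=3,
        )
        with pytest.warns(IdentifiabilityWarning):
            fit_parameters(
                ds, params, ["k_tx_R", "K_tetR", "k_agg"],
                schedule=schedule, seed=0, n_starts=1,
            )

    def test_unknown_free_parameter_rejected(self, clean_dataset, params, schedule):
        with pytest.raises(CircuitError, match="unknown free parameter"):
            fit_parameters(clean_dataset, params, ["k_bogus"], schedule=schedule)

    def test_objective_invariant_to_record_order(self, clean_dataset, params, schedule):
        floor = _log_floor(clean_dataset)
        r1, _ = _residual_vector(
            params, clean_dataset, STANDARD_VARIANTS, schedule, FIT_SOLVER, floor
        )
        shuffled = TimeCourseDataset(
            records=clean_dataset.records.sample(frac=1.0, random_state=5).reset_index(drop=True),
            fractions=clean_dataset.fractions,
        )
        r2, _ = _residual_vector(
            params, shuffled, STANDARD_VARIANTS, schedule, FIT_SOLVER, floor
        )
        assert np.sum(r1**2) == pytest.approx(np.sum(r2**2), rel=1e-12)


class TestLocalSensitivity:
    def test_unwired_parameter_has_zero_sensitivity(self, params, schedule):
        rep = local_sensitivity(
            params, STANDARD_VARIANTS["NO_FB"], schedule,
            outputs=("total_gfp",), parameters=["k_tx_R", "K_tetR"],
        )
        assert rep.coefficients.loc["k_tx_R", "total_gfp"] == 0.0
        assert rep.coefficients.loc["K_tetR", "total_gfp"] == 0.0

    def test_fluorescence_scaling_is_exactly_minus_one(self, params, schedule):
        rep = local_sensitivity(
            params, STANDARD_VARIANTS["WT_STRONG"], schedule,
            outputs=("fluorescence_equiv",), parameters=["c_fluor"],
        )
        assert rep.coefficients.loc["c_fluor", "fluorescence_equiv"] == pytest.approx(
            -1.0, abs=1e-9
        )

    def test_ranking_stable_across_step_sizes(self, params, schedule):
        pars = ["k_tx_G", "k_tl_G", "K_tetR", "k_agg", "k_fold", "mu0"]
        reps = {
            h: local_sensitivity(
                params, STANDARD_VARIANTS["WT_STRONG"], schedule,
                perturbation=h, parameters=pars,
            )
            for h in (0.01, 0.05)
        }
        assert reps[0.01].top(2) == reps[0.05].top(2)

    def test_coefficients_converge_with_step(self, params, schedule):
        pars = ["k_agg"]
        s1 = local_sensitivity(
            params, STANDARD_VARIANTS["NO_FB"], schedule, perturbation=0.02, parameters=pars
        ).coefficients
        s2 = local_sensitivity(
            params, STANDARD_VARIANTS["NO_FB"], schedule, perturbation=0.04, parameters=pars
        ).coefficients
        assert s1.loc["k_agg", "total_gfp"] == pytest.approx(
            s2.loc["k_agg", "total_gfp"], rel=0.02, abs=1e-4
        )

    def test_invalid_perturbation_rejected(self, params, schedule):
        with pytest.raises(CircuitError):
            local_sensitivity(params, STANDARD_VARIANTS["NO_FB"], schedule, perturbation=0.9)


class TestCrossValidation:
    def test_leave_one_clone_out_bookkeeping(self, params, schedule):
        ds = generate_timecourse(
            params, STANDARD_VARIANTS["WT_STRONG"], schedule, np.arange(0.0, 12.5, 2.0),
            n_clones=4, noise=NO_NOISE, clone_var=NO_VAR, seed=11,
        )
        rep = cross_validate(
            ds, ["k_tx_G"], k=4, unit="clone", seed=0, init=params,
            schedule=schedule, n_starts=1,
        )
        assert len(rep.folds) == 4
        held = sorted(u for fold in rep.folds for u in fold)
        assert held == ds.clones  # each clone held out exactly once

    def test_noiseless_errors_vanish(self, params, schedule):
        ds = generate_timecourse(
            params, STANDARD_VARIANTS["WT_STRONG"], schedule, np.arange(0.0, 12.5, 2.0),
            n_clones=4, noise=NO_NOISE, clone_var=NO_VAR, seed=12,
        )
        rep = cross_validate(
            ds, ["k_tx_G"], k=2, unit="clone", seed=0, init=params,
            schedule=schedule, n_starts=1,
        )
        assert rep.summary["mean_train_error"] < 1e-8
        assert rep.summary["mean_test_error"] < 1e-8

    def test_too_many_folds_rejected(self, params, schedule):
        ds = generate_timecourse(
            params, STANDARD_VARIANTS["WT_STRONG"], schedule, [4.0, 8.0],
            n_clones=2, noise=NO_NOISE, clone_var=NO_VAR, seed=13,
        )
        with pytest.raises(CircuitError, match="exceeds the number"):
            cross_validate(ds, ["k_tx_G"], k=5, unit="clone", init=params, schedule=schedule)
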