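"""Model inversion: imputation, bounds, objective and the global search."""

import numpy as np
import pandas as pd
import pytest

from spraydry.datasets import true_d50
from spraydry.encoding import NOZZLE_COLUMN, SprayFeatureEncoder
from spraydry.inversion import (
    InversionProblem,
    derive_bounds,
    fit_scale_spc,
    impute_process_parameters,
    invert,
    objective,
    objective_value,
    propose,
)
from spraydry.schema import PROCESS_PARAMS, SOLVENT_PREFIX


def _problem_from_row(row, dataset, target=None, **kwargs):
    formulation = {
        "polymer_type": row["polymer_type"],
        "active_loading": row["active_loading"],
        "polymer_loading": row["polymer_loading"],
        "solids_content": row["solids_content"],
    }
    for c in dataset.columns:
        if c.startswith(SOLVENT_PREFIX):
            formulation[c] = row[c]
    return InversionProblem(
        formulation=formulation,
        dryer_scale=row["dryer_scale"],
        target_d50=target if target is not None else float(row["d50"]),
        **kwargs,
    )


@pytest.fixture(scope="module")
def inv_world(default_world):
    w = default_world
    spcs = fit_scale_spc(w.train, w.encoder.state_, seed=0)
    return w, spcs


class TestObjectiveArithmetic:
    def test_zero_at_perfect_feasible_prediction(self):
        assert objective_value(40.0, 40.0, t2=1.0, q=0.5, t2_ucl=10.0, q_ucl=5.0) == 0.0

    def test_q_penalty_at_twice_the_limit(self):
        # |y - yhat| = 2, Q = 2 Q_UCL, T2 within limit -> J = 2 + 100*(2-1) = 102
        assert objective_value(40.0, 42.0, t2=1.0, q=10.0, t2_ucl=10.0, q_ucl=5.0) == pytest.approx(102.0)

    def test_penalty_is_zero_exactly_at_the_limit(self):
        assert objective_value(40.0, 40.0, t2=10.0, q=5.0, t2_ucl=10.0, q_ucl=5.0) == 0.0

    def test_penalty_continuous_and_increasing_beyond_limit(self):
        eps = 1e-9
        at = objective_value(0, 0, t2=0, q=5.0, t2_ucl=1.0, q_ucl=5.0)
        just_over = objective_value(0, 0, t2=0, q=5.0 + eps, t2_ucl=1.0, q_ucl=5.0)
        assert at == 0.0 and just_over < 1e-6
        grid = [objective_value(0, 0, t2=0, q=q, t2_ucl=1.0, q_ucl=5.0) for q in (6, 7, 9)]
        assert grid[0] < grid[1] < grid[2]


class TestImputation:
    def test_user_fixed_everything_returned_unchanged(self, inv_world):
        (w, _) = inv_world
        row = w.test.iloc[0]
        fixed = {p: 1.234 for p in PROCESS_PARAMS}
        fixed[NOZZLE_COLUMN] = 33.3
        prob = _problem_from_row(row, w.dataset, user_fixed=fixed)
        est = impute_process_parameters(prob, w.train, w.encoder.state_, seed=0)
        assert est == fixed

    def test_nozzle_encoding_clipped_to_target_band(self, inv_world):
        (w, _) = inv_world
        row = w.test.iloc[3]
        prob = _problem_from_row(row, w.dataset, target=40.0)
        est = impute_process_parameters(prob, w.train, w.encoder.state_, seed=0)
        assert 30.0 <= est[NOZZLE_COLUMN] <= 50.0

    def test_estimates_stay_within_scale_training_range(self, inv_world):
        (w, _) = inv_world
        row = w.test.iloc[5]
        prob = _problem_from_row(row, w.dataset)
        est = impute_process_parameters(prob, w.train, w.encoder.state_, seed=0)
        scale_train = w.train[w.train["dryer_scale"] == row["dryer_scale"]]
        for p in PROCESS_PARAMS:
            assert scale_train[p].min() - 1e-9 <= est[p] <= scale_train[p].max() + 1e-9

    def test_linear_relation_recovered(self):
        """When every process parameter is an exact linear function of D50
        and solids, round-robin regression imputation solves the system."""
        rng = np.random.default_rng(0)
        n = 120
        d50 = rng.uniform(20, 60, n)
        solids = rng.uniform(5, 25, n)
        frame = pd.DataFrame(
            {
                "api_id": "A",
                "polymer_type": "HPMCAS M",
                "nozzle_id": "N0",
                "dryer_scale": "PSD-1",
                "active_loading": 50.0,
                "polymer_loading": 5.0,
                "solids_content": solids,
                "solvent_acetone": 100.0,
                "inlet_temp": 60.0 + 1.2 * d50 + 0.5 * solids,
                "outlet_temp": 20.0 + 0.4 * d50,
                "drying_gas_flow": 800.0 + 20.0 * d50,
                "solution_to_gas_ratio": 0.02 + 0.002 * d50,
                "atomization_pressure": 5.0 - 0.05 * d50,
                "d50": d50,
            }
        )
        enc = SprayFeatureEncoder().fit(frame)
        target = 45.0
        prob = InversionProblem(
            formulation={
                "polymer_type": "HPMCAS M", "active_loading": 50.0,
                "polymer_loading": 5.0, "solids_content": 15.0,
                "solvent_acetone": 100.0,
            },
            dryer_scale="PSD-1",
            target_d50=target,
        )
        est = impute_process_parameters(prob, frame, enc.state_, seed=0, regressor="bayesian")
        expected = {
            "inlet_temp": 60.0 + 1.2 * target + 0.5 * 15.0,
            "outlet_temp": 20.0 + 0.4 * target,
            "drying_gas_flow": 800.0 + 20.0 * target,
            "solution_to_gas_ratio": 0.02 + 0.002 * target,
            "atomization_pressure": 5.0 - 0.05 * target,
        }
        for p, value in expected.items():
            span = frame[p].max() - frame[p].min()
            assert abs(est[p] - value) <= 1e-3 * span, p

    def test_missing_scale_rows_error(self, inv_world):
        (w, _) = inv_world
        row = w.test.iloc[0]
        prob = _problem_from_row(row, w.dataset)
        only_other = w.train[w.train["dryer_scale"] != row["dryer_scale"]]
        with pytest.raises(ValueError, match="scale"):
            impute_process_parameters(prob, only_other, w.encoder.state_, seed=0)


class TestDeriveBounds:
    def _prob(self, **kwargs):
        return InversionProblem(
            formulation={"polymer_type": "None", "active_loading": 100.0,
                         "polymer_loading": 0.0, "solids_content": 10.0},
            dryer_scale="PSD-1", target_d50=40.0, **kwargs,
        )

    def test_multipliers(self):
        est = {"inlet_temp": 100.0, "outlet_temp": 40.0, "drying_gas_flow": 1000.0,
               "solution_to_gas_ratio": 0.1, "atomization_pressure": 2.0,
               NOZZLE_COLUMN: 40.0}
        bounds = derive_bounds(est, self._prob())
        assert bounds["inlet_temp"] == pytest.approx((90.0, 110.0))
        assert bounds["atomization_pressure"] == pytest.approx((1.0, 3.0))
        assert bounds[NOZZLE_COLUMN] == pytest.approx((30.0, 50.0))

    def test_user_fixed_collapses_to_point(self):
        est = {p: 1.0 for p in PROCESS_PARAMS}
        est[NOZZLE_COLUMN] = 40.0
        bounds = derive_bounds(est, self._prob(user_fixed={"solution_to_gas_ratio": 0.05}))
        assert bounds["solution_to_gas_ratio"] == (0.05, 0.05)

    def test_user_bounds_override_and_validation(self):
        est = {p: 1.0 for p in PROCESS_PARAMS}
        est[NOZZLE_COLUMN] = 40.0
        bounds = derive_bounds(est, self._prob(user_bounds={"inlet_temp": (70, 80)}))
        assert bounds["inlet_temp"] == (70.0, 80.0)
        with pytest.raises(ValueError, match="inlet_temp"):
            derive_bounds(est, self._prob(user_bounds={"inlet_temp": (90, 80)}))


class TestInvert:
    def test_single_free_parameter_against_grid_oracle(self, inv_world):
        """With only pressure free, the sampler must match a dense 1-D grid."""
        w, spcs = inv_world
        row = w.test.iloc[1]
        spc = spcs[row["dryer_scale"]]
        fixed = {p: float(row[p]) for p in PROCESS_PARAMS if p != "atomization_pressure"}
        fixed[NOZZLE_COLUMN] = float(
            w.encoder.state_.nozzle_lookup.get(row["nozzle_id"],
                                              w.encoder.state_.global_mean_d50)
        )
        prob = _problem_from_row(row, w.dataset, user_fixed=fixed)
        bounds = dict({p: (v, v) for p, v in fixed.items()})
        lo, hi = 0.5 * row["atomization_pressure"], 1.5 * row["atomization_pressure"]
        bounds["atomization_pressure"] = (lo, hi)
        # epsilon=0 disables the early stop so the full budget is spent and
        # the comparison with the dense grid is meaningful
        result = invert(prob, w.ensemble, spc, w.encoder.state_, bounds, budget=200,
                        epsilon=0.0, seed=0)
        grid = np.linspace(lo, hi, 2001)
        grid_J = [
            objective(dict(fixed, atomization_pressure=float(p)), prob, w.ensemble, spc,
                      w.encoder.state_)
            for p in grid
        ]
        assert result.objective <= min(grid_J) + 0.05 * prob.target_d50
        # the sampler must not report a better-than-possible miss either
        assert abs(result.predicted_d50 - prob.target_d50) <= min(grid_J) + 0.05 * prob.target_d50

    def test_unreachable_target_reports_failure_with_best_effort(self, inv_world):
        w, spcs = inv_world
        row = w.test.iloc[2]
        prob = _problem_from_row(row, w.dataset, target=500.0)  # far beyond reachable
        result = propose(prob, w.ensemble, w.encoder.state_, w.train, spc_models=spcs, seed=0)
        assert not result.success
        assert np.isfinite(result.predicted_d50)

    def test_scale_up_mode_leaves_fixed_parameters_untouched(self, inv_world):
        """Scale-up: ratio and nozzle encoding carried over from the pilot
        run are never modified by imputation or optimization."""
        w, spcs = inv_world
        psd2 = w.test[w.test["dryer_scale"] == "PSD-2"]
        row = psd2.iloc[0]
        fixed = {
            "solution_to_gas_ratio": float(row["solution_to_gas_ratio"]),
            NOZZLE_COLUMN: 42.0,
        }
        prob = _problem_from_row(row, w.dataset, user_fixed=fixed)
        result = propose(prob, w.ensemble, w.encoder.state_, w.train, spc_models=spcs, seed=0)
        assert result.params["solution_to_gas_ratio"] == fixed["solution_to_gas_ratio"]
        assert result.params[NOZZLE_COLUMN] == fixed[NOZZLE_COLUMN]

    def test_reported_diagnostics_are_self_consistent(self, inv_world):
        w, spcs = inv_world
        row = w.test.iloc[4]
        spc = spcs[row["dryer_scale"]]
        prob = _problem_from_row(row, w.dataset)
        result = propose(prob, w.ensemble, w.encoder.state_, w.train, spc_models=spcs, seed=0)
        # J re-evaluates to the reported value
        J = objective(result.params, prob, w.ensemble, spc, w.encoder.state_)
        assert J == pytest.approx(result.objective, abs=1e-9)
        # success flag recomputable from the diagnostics
        expected = (
            abs(result.predicted_d50 - prob.target_d50) <= 0.10 * prob.target_d50
            and result.t2 <= spc.t2_ucl
            and result.q <= spc.q_ucl
        )
        assert result.success == expected

    def test_budget_validation(self, inv_world):
        w, spcs = inv_world
        row = w.test.iloc[0]
        prob = _problem_from_row(row, w.dataset)
        with pytest.raises(ValueError):
            invert(prob, w.ensemble, spcs[row["dryer_scale"]], w.encoder.state_,
                   {p: (0.0, 1.0) for p in (*PROCESS_PARAMS, NOZZLE_COLUMN)}, budget=5)


def test_forward_oracle_round_trip_single_problem(inv_world):
    """One full inversion checked against the generator's forward law."""
    w, spcs = inv_world
    row = w.test.iloc[6]
    target = true_d50(row, w.truth)
    prob = _problem_from_row(row, w.dataset, target=target)
    result = propose(prob, w.ensemble, w.encoder.state_, w.train, spc_models=spcs, seed=0)
    nz = min(
        w.encoder.state_.nozzle_lookup,
        key=lambda n: abs(w.encoder.state_.nozzle_lookup[n] - result.params[NOZZLE_COLUMN]),
    )
    record = dict(prob.formulation)
    record.update(
        nozzle_id=nz, dryer_scale=row["dryer_scale"],
        solution_to_gas_ratio=result.params["solution_to_gas_ratio"],
        atomization_pressure=result.params["atomization_pressure"],
    )
    forward = true_d50(record, w.truth)
    assert abs(forward - target) / target <= 0.5  # loose single-problem sanity
    assert result.nearest_nozzles[0] == nz
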