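"""Model inversion: propose "first to try" process parameters for a target D50.

Given a fixed formulation, a dryer scale and a target median particle size y,
the inversion runs in two phases:

1.  *Imputation* — the process parameters are treated as missing data. The
    problem row (formulation + target D50 known, process parameters missing)
    is appended to the scale-matched training data; each missing parameter is
    initialized to the training mean and repeatedly re-predicted, in
    randomized order, by a shrunken linear regressor on all other columns
    (including D50 and previously imputed values). Estimates are clipped to
    the training range each pass — except the nozzle encoding, which is
    clipped to [0.75, 1.25] x target D50. The result seeds the search bounds.

2.  *Penalized global optimization* — process parameters are searched within
    bounds derived from the imputed values (x[0.90, 1.10] for temperatures,
    gas flow and solution-to-gas ratio; x[0.50, 1.50] for atomization
    pressure; x[0.75, 1.25] for the nozzle encoding), minimizing

        J = |y - yhat| + 100 H(Q - Q_UCL)(Q/Q_UCL - 1)
                       + 100 H(T2 - T2_UCL)(T2/T2_UCL - 1)

    where yhat is the ensemble prediction, H the Heaviside step (H(x)=1 for
    x>0 else 0), and Q/T2 come from the per-scale PCA control model — so
    candidates that break the historical correlation structure pay a penalty
    that starts at zero exactly at the control limit and grows linearly.
    The search uses the DIRECT space-partitioning sampler (deterministic),
    stopping early once J falls below epsilon (default 10% of the target).

An inversion is *successful* when the predicted size is within 10% of the
target and neither control limit is exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import direct
from sklearn.linear_model import BayesianRidge, Ridge

from .encoding import (
    NOZZLE_COLUMN,
    SCALE_COLUMN,
    EncoderState,
    apply_minmax,
    encode_composition,
)
from .schema import FORMULATION_NUMERIC, PROCESS_PARAMS, SOLVENT_PREFIX, solvent_column
from .spc import SPCModel, fit_spc, t2_q

__all__ = [
    "InversionProblem",
    "InversionResult",
    "impute_process_parameters",
    "derive_bounds",
    "fit_scale_spc",
    "objective",
    "objective_value",
    "invert",
    "propose",
]

#: Searchable parameters, canonical order (nozzle enters via its encoding).
INVERSION_PARAMS = (*PROCESS_PARAMS, NOZZLE_COLUMN)

#: Bound multipliers applied to the imputed estimates.
BOUND_MULTIPLIERS = {
    "inlet_temp": (0.90, 1.10),
    "outlet_temp": (0.90, 1.10),
    "drying_gas_flow": (0.90, 1.10),
    "solution_to_gas_ratio": (0.90, 1.10),
    "atomization_pressure": (0.50, 1.50),
    NOZZLE_COLUMN: (0.75, 1.25),
}

NOZZLE_CLIP = (0.75, 1.25)  # x target D50, during imputation

#: Columns the per-scale PCA control model is built on. Numeric formulation
#: attributes + process parameters + nozzle encoding: the sparse one-hot
#: composition columns are excluded — at per-scale sample sizes a PCA over
#: near-binary indicators flags every unseen-but-legitimate chemistry
#: combination as a correlation-structure violation.
SPC_FEATURES = (*FORMULATION_NUMERIC, *PROCESS_PARAMS, NOZZLE_COLUMN)


@dataclass
class InversionProblem:
    """Fixed formulation + scale + target D50, with optional user overrides.

    ``formulation`` carries polymer_type, active_loading, polymer_loading,
    solids_content and solvent fractions (wt% of solvent system, keyed by
    solvent name or ``solvent_*`` column name).
    """

    formulation: dict
    dryer_scale: str
    target_d50: float
    user_fixed: dict = field(default_factory=dict)
    user_bounds: dict = field(default_factory=dict)
    api_id: str = "candidate"

    def __post_init__(self):
        if not self.target_d50 > 0:
            raise ValueError("target_d50 must be positive")
        bad = set(self.user_fixed) - set(INVERSION_PARAMS)
        if bad:
            raise ValueError(f"user_fixed keys must be process parameters, got {sorted(bad)}")

    def record_frame(self, params: dict | None = None) -> pd.DataFrame:
        """One-row raw record frame for feature assembly."""
        row = {
            "api_id": self.api_id,
            "polymer_type": self.formulation.get("polymer_type", "None"),
            "nozzle_id": "__candidate__",
            "dryer_scale": self.dryer_scale,
            "active_loading": self.formulation.get("active_loading", 0.0),
            "polymer_loading": self.formulation.get("polymer_loading", 0.0),
            "solids_content": self.formulation.get("solids_content", 0.0),
        }
        for key, value in self.formulation.items():
            if key.startswith(SOLVENT_PREFIX):
                row[key] = value
            elif key not in row:
                row[solvent_column(key)] = value
        for p in PROCESS_PARAMS:
            row[p] = (params or {}).get(p, np.nan)
        return pd.DataFrame([row])


@dataclass
class InversionResult:
    params: dict  # process parameters + nozzle encoding
    predicted_d50: float
    objective: float
    t2: float
    q: float
    success: bool
    bounds: dict
    iterations: int
    nearest_nozzles: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {f"param.{k}": v for k, v in self.params.items()}
        out.update(
            predicted_d50=self.predicted_d50,
            objective=self.objective,
            t2=self.t2,
            q=self.q,
            success=self.success,
            iterations=self.iterations,
        )
        return out


def candidate_features(
    problem: InversionProblem, params: dict, state: EncoderState
) -> pd.DataFrame:
    """Scaled one-row feature frame for a candidate parameter set."""
    records = problem.record_frame(params)
    matrix = encode_composition(records, state)
    if state.use_target_encoding:
        matrix[NOZZLE_COLUMN] = params[NOZZLE_COLUMN]
    matrix = matrix[state.feature_columns]
    if state.minmax:
        matrix = apply_minmax(matrix, state.minmax)
    return matrix


def _imputation_table(train: pd.DataFrame, state: EncoderState) -> pd.DataFrame:
    """Unscaled working table for imputation: composition + process columns
    + nozzle encoding + d50 (scale indicator dropped — single-scale data)."""
    table = encode_composition(train, state).drop(columns=[SCALE_COLUMN])
    table[NOZZLE_COLUMN] = [
        state.nozzle_lookup.get(str(nz), state.global_mean_d50) for nz in train["nozzle_id"]
    ]
    table["d50"] = train["d50"].to_numpy(dtype=float)
    return table


def impute_process_parameters(
    problem: InversionProblem,
    train: pd.DataFrame,
    state: EncoderState,
    n_iterations: int = 20,
    seed: int = 0,
    regressor: str = "ridge",
    tol: float = 1e-4,
) -> dict:
    """Phase-1 estimates of the process parameters (incl. nozzle encoding).

    Round-robin regression imputation on scale-matched training data; stops
    after ``n_iterations`` passes or when the largest parameter change falls
    below ``tol`` of that parameter's training range.
    """
    scale_train = train[train["dryer_scale"] == problem.dryer_scale]
    if len(scale_train) == 0:
        raise ValueError(f"no training rows for dryer scale {problem.dryer_scale!r}")
    rng = np.random.default_rng(seed)
    table = _imputation_table(scale_train, state)
    lo, hi = table.min(), table.max()

    missing = [p for p in INVERSION_PARAMS if p not in problem.user_fixed]
    new_row = {}
    prob_features = encode_composition(problem.record_frame(), state).iloc[0]
    for col in table.columns:
        if col == "d50":
            new_row[col] = problem.target_d50
        elif col in problem.user_fixed:
            new_row[col] = float(problem.user_fixed[col])
        elif col in missing:
            new_row[col] = float(table[col].mean())  # initialized to training mean
        else:
            new_row[col] = float(prob_features.get(col, 0.0))

    def clip(p, value):
        if p == NOZZLE_COLUMN:
            return float(
                np.clip(value, NOZZLE_CLIP[0] * problem.target_d50,
                        NOZZLE_CLIP[1] * problem.target_d50)
            )
        return float(np.clip(value, lo[p], hi[p]))

    make_reg = {"ridge": lambda: Ridge(alpha=1.0), "bayesian": BayesianRidge}[regressor]
    X_cols = list(table.columns)
    for _ in range(n_iterations):
        max_change = 0.0
        for p in rng.permutation(missing):
            others = [c for c in X_cols if c != p]
            reg = make_reg().fit(table[others].to_numpy(), table[p].to_numpy())
            pred = float(reg.predict(np.array([[new_row[c] for c in others]]))[0])
            pred = clip(p, pred)
            span = max(hi[p] - lo[p], 1e-12)
            max_change = max(max_change, abs(pred - new_row[p]) / span)
            new_row[p] = pred
        if max_change < tol:
            break
    return {p: new_row[p] for p in INVERSION_PARAMS}


def derive_bounds(estimates: dict, problem: InversionProblem) -> dict:
    """Per-parameter (lo, hi) search bounds from the imputed estimates;
    user bounds override, user-fixed parameters collapse to a point."""
    bounds = {}
    for p in INVERSION_PARAMS:
        if p in problem.user_fixed:
            v = float(problem.user_fixed[p])
            bounds[p] = (v, v)
            continue
        if p in problem.user_bounds:
            lo, hi = map(float, problem.user_bounds[p])
        else:
            m_lo, m_hi = BOUND_MULTIPLIERS[p]
            lo, hi = m_lo * estimates[p], m_hi * estimates[p]
        if lo > hi:
            raise ValueError(f"bounds for {p!r} have lo > hi ({lo} > {hi})")
        bounds[p] = (lo, hi)
    return bounds


def fit_scale_spc(
    train: pd.DataFrame,
    state: EncoderState,
    alpha: float = 0.9973,
    seed: int = 0,
    features=SPC_FEATURES,
) -> dict[str, SPCModel]:
    """Per-scale SPC models on scaled model features (see SPC_FEATURES;
    the scale indicator is constant within a scale and always excluded)."""
    from .encoding import build_features

    models = {}
    for scale, subset in train.groupby("dryer_scale"):
        feats = build_features(subset, state)[list(features)]
        models[str(scale)] = fit_spc(feats, alpha=alpha, seed=seed)
    return models


def _heaviside(x: float) -> float:
    return 1.0 if x > 0 else 0.0


def objective_value(
    y: float, yhat: float, t2: float, q: float, t2_ucl: float, q_ucl: float
) -> float:
    """J = |y - yhat| + 100 H(Q - Q_UCL)(Q/Q_UCL - 1) + 100 H(T2 - T2_UCL)(T2/T2_UCL - 1).

    Penalties are zero at the control limit (H gates them) and increase
    linearly beyond it.
    """
    return (
        abs(y - yhat)
        + 100.0 * _heaviside(q - q_ucl) * (q / q_ucl - 1.0)
        + 100.0 * _heaviside(t2 - t2_ucl) * (t2 / t2_ucl - 1.0)
    )


def _evaluate(params, problem, model, spc, state):
    feats = candidate_features(problem, params, state)
    yhat = float(np.asarray(model.predict(np.asarray(feats, dtype=float))).ravel()[0])
    t2, q = t2_q(feats[list(spc.feature_names)].iloc[0].to_numpy(), spc)
    return objective_value(problem.target_d50, yhat, t2, q, spc.t2_ucl, spc.q_ucl), yhat, t2, q


def objective(
    params: dict, problem: InversionProblem, model, spc: SPCModel, state: EncoderState
) -> float:
    """The penalized inversion objective J at one candidate."""
    return _evaluate(params, problem, model, spc, state)[0]


class _EarlyStop(Exception):
    pass


def invert(
    problem: InversionProblem,
    model,
    spc: SPCModel,
    state: EncoderState,
    bounds: dict,
    budget: int = 200,
    epsilon: float | None = None,
    seed: int = 0,
) -> InversionResult:
    """Minimize J within ``bounds`` with the DIRECT sampler.

    ``budget`` caps objective evaluations; the search stops early once
    J < epsilon (default 0.10 * target). Fixed parameters (point bounds) are
    excluded from the search space.
    """
    if budget < 10:
        raise ValueError("budget must be >= 10")
    eps_stop = 0.10 * problem.target_d50 if epsilon is None else epsilon
    free = [p for p in INVERSION_PARAMS if bounds[p][0] < bounds[p][1]]
    fixed = {p: bounds[p][0] for p in INVERSION_PARAMS if p not in free}

    best = {"J": np.inf, "params": None, "yhat": np.nan, "t2": np.nan, "q": np.nan}
    n_evals = 0

    def fun(x):
        nonlocal n_evals
        params = dict(fixed)
        params.update({p: float(v) for p, v in zip(free, x)})
        J, yhat, t2, q = _evaluate(params, problem, model, spc, state)
        n_evals += 1
        if J < best["J"]:
            best.update(J=J, params=params, yhat=yhat, t2=t2, q=q)
        if J < eps_stop:
            raise _EarlyStop
        return J

    if free:
        try:
            direct(
                fun,
                [bounds[p] for p in free],
                maxfun=budget,
                maxiter=10 * budget,
                locally_biased=True,
            )
        except _EarlyStop:
            pass
    else:
        fun(np.array([]))

    y = problem.target_d50
    success = (
        abs(best["yhat"] - y) <= 0.10 * y
        and best["t2"] <= spc.t2_ucl
        and best["q"] <= spc.q_ucl
    )
    nearest = sorted(
        state.nozzle_lookup,
        key=lambda nz: abs(state.nozzle_lookup[nz] - best["params"][NOZZLE_COLUMN]),
    )[:3]
    return InversionResult(
        params=best["params"],
        predicted_d50=best["yhat"],
        objective=best["J"],
        t2=best["t2"],
        q=best["q"],
        success=bool(success),
        bounds=dict(bounds),
        iterations=n_evals,
        nearest_nozzles=nearest,
    )


def propose(
    problem: InversionProblem,
    model,
    state: EncoderState,
    train: pd.DataFrame,
    spc_models: dict[str, SPCModel] | None = None,
    n_imputation: int = 20,
    budget: int = 200,
    epsilon: float | None = None,
    seed: int = 0,
) -> InversionResult:
    """End-to-end inversion: impute -> derive bounds -> optimize."""
    spc_models = spc_models or fit_scale_spc(train, state, seed=seed)
    spc = spc_models[problem.dryer_scale]
    estimates = impute_process_parameters(
        problem, train, state, n_iterations=n_imputation, seed=seed
    )
    bounds = derive_bounds(estimates, problem)
    return invert(
        problem, model, spc, state, bounds, budget=budget, epsilon=epsilon, seed=seed
    )
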