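"""Feature encoding for spray records.

Raw records become a numeric feature matrix via three steps, all fitted on
training data only (the encoder is the main leakage surface of the whole
pipeline, since the nozzle encoding is a function of the target):

1.  *Composition encoding*: one column per polymer and solvent seen in
    training, holding the component's weight percent when present in the
    record and 0 otherwise, plus numeric pass-through columns and a 0/1
    dryer-scale indicator (PSD-2 = 1).
2.  *Nozzle target encoding with additive smoothing*: each nozzle maps to
    ``lam * m_c + (1 - lam) * m_global`` where ``m_c`` is the mean training
    D50 for that nozzle over ``n`` sprays, ``m_global`` the overall training
    mean, and ``lam = 1 / (1 + exp(-(n - k) / f))`` — a logistic shrinkage
    that trusts the per-nozzle mean only once enough sprays support it.
    Defaults k=1, f=3. Nozzles unseen in training fall back to the global
    mean (a first-class path: new nozzles are routine at predict time).
3.  *Min–max scaling* to the training range; test rows may fall outside
    [0, 1] (no clipping — extrapolation is signal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import schema
from .schema import FORMULATION_NUMERIC, PROCESS_PARAMS, SOLVENT_PREFIX

log = logging.getLogger("spraydry")

NOZZLE_COLUMN = "nozzle_encoded"
ORIFICE_COLUMN = "orifice_diameter"
SCALE_COLUMN = "scale_psd2"


@dataclass
class EncoderState:
    """Everything fitted during encoding, serializable to a flat file."""

    polymer_columns: list[str] = field(default_factory=list)
    solvent_columns: list[str] = field(default_factory=list)
    nozzle_lookup: dict[str, float] = field(default_factory=dict)
    global_mean_d50: float = float("nan")
    smoothing_k: int = 1
    smoothing_f: float = 3.0
    minmax: dict[str, tuple[float, float]] = field(default_factory=dict)
    use_target_encoding: bool = True
    include_orifice_diameter: bool = False
    orifice_diameters: dict[str, float] = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        cols = [
            *FORMULATION_NUMERIC,
            *self.polymer_columns,
            *self.solvent_columns,
            *PROCESS_PARAMS,
        ]
        if self.use_target_encoding:
            cols.append(NOZZLE_COLUMN)
        if self.include_orifice_diameter:
            cols.append(ORIFICE_COLUMN)
        cols.append(SCALE_COLUMN)
        return cols

    def save(self, path) -> None:
        lines = [
            f"smoothing_k={self.smoothing_k!r}",
            f"smoothing_f={self.smoothing_f!r}",
            f"global_mean_d50={self.global_mean_d50!r}",
            f"use_target_encoding={int(self.use_target_encoding)}",
            f"include_orifice_diameter={int(self.include_orifice_diameter)}",
            "polymer_columns=" + ",".join(self.polymer_columns),
            "solvent_columns=" + ",".join(self.solvent_columns),
        ]
        for nz, val in sorted(self.nozzle_lookup.items()):
            lines.append(f"nozzle.{nz}={val!r}")
        for nz, val in sorted(self.orifice_diameters.items()):
            lines.append(f"orifice.{nz}={val!r}")
        for col, (lo, hi) in self.minmax.items():
            lines.append(f"minmax.{col}={lo!r},{hi!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "EncoderState":
        state = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("=")
            if key == "smoothing_k":
                state.smoothing_k = int(value)
            elif key == "smoothing_f":
                state.smoothing_f = float(value)
            elif key == "global_mean_d50":
                state.global_mean_d50 = float(value)
            elif key == "use_target_encoding":
                state.use_target_encoding = bool(int(value))
            elif key == "include_orifice_diameter":
                state.include_orifice_diameter = bool(int(value))
            elif key == "polymer_columns":
                state.polymer_columns = [c for c in value.split(",") if c]
            elif key == "solvent_columns":
                state.solvent_columns = [c for c in value.split(",") if c]
            elif key.startswith("nozzle."):
                state.nozzle_lookup[key[7:]] = float(value)
            elif key.startswith("orifice."):
                state.orifice_diameters[key[8:]] = float(value)
            elif key.startswith("minmax."):
                lo, hi = value.split(",")
                state.minmax[key[7:]] = (float(lo), float(hi))
        return state


def smoothing_weight(n: float, k: float, f: float) -> float:
    """Logistic shrinkage weight lam = 1 / (1 + exp(-(n - k) / f))."""
    return 1.0 / (1.0 + math.exp(-(n - k) / f))


def fit_target_encoding(
    train: pd.DataFrame, k: int = 1, f: float = 3.0
) -> tuple[dict[str, float], float]:
    """Fit the smoothed nozzle target encoding on training rows.

    Every row must carry a D50. Returns (lookup, global_mean); the lookup
    covers every training nozzle, and unseen nozzles should use the global
    mean. Encoded values are convex combinations of per-nozzle and global
    means, hence bounded by the training D50 range.
    """
    if len(train) == 0:
        raise ValueError("cannot fit target encoding on an empty training set")
    if k < 0 or f <= 0:
        raise ValueError("smoothing parameters require k >= 0 and f > 0")
    d50 = train["d50"]
    if d50.isna().any():
        raise ValueError("every training record needs a d50 for target encoding")
    global_mean = float(d50.mean())
    lookup = {}
    for nozzle, group in train.groupby("nozzle_id", sort=True)["d50"]:
        lam = smoothing_weight(len(group), k, f)
        lookup[str(nozzle)] = lam * float(group.mean()) + (1.0 - lam) * global_mean
    return lookup, global_mean


def encode_composition(records: pd.DataFrame, state: EncoderState) -> pd.DataFrame:
    """Unscaled feature matrix: composition columns + numeric pass-throughs
    + 0/1 scale indicator. Categories unseen in training map to zeros in the
    known columns (logged, never an error)."""
    out = pd.DataFrame(index=records.index)
    for col in FORMULATION_NUMERIC:
        out[col] = records[col].astype(float)
    for col in state.polymer_columns:
        out[col] = 0.0
    for i, polymer in enumerate(records["polymer_type"]):
        if polymer == "None":
            continue
        col = schema.polymer_column(str(polymer))
        if col in state.polymer_columns:
            out.iloc[i, out.columns.get_loc(col)] = float(records["polymer_loading"].iloc[i])
        else:
            log.info("polymer %r unseen in training; encoded as zeros", polymer)
    present_solvents = [c for c in records.columns if c.startswith(SOLVENT_PREFIX)]
    for col in state.solvent_columns:
        out[col] = records[col].astype(float) if col in present_solvents else 0.0
    for col in present_solvents:
        if col not in state.solvent_columns and (records[col] != 0).any():
            log.info("solvent column %r unseen in training; dropped", col)
    for col in PROCESS_PARAMS:
        out[col] = records[col].astype(float)
    out[SCALE_COLUMN] = (records["dryer_scale"] == "PSD-2").astype(float)
    return out


def fit_minmax(matrix: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-column training (min, max). Apply maps x -> (x - min)/(max - min);
    constant columns map to 0.0 by convention."""
    if len(matrix) == 0:
        raise ValueError("cannot fit min-max scaling on an empty matrix")
    return {col: (float(matrix[col].min()), float(matrix[col].max())) for col in matrix.columns}


def apply_minmax(matrix: pd.DataFrame, minmax: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = matrix.copy()
    for col in out.columns:
        lo, hi = minmax[col]
        out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
    return out


def encode_nozzles(records: pd.DataFrame, state: EncoderState) -> pd.Series:
    values = [
        state.nozzle_lookup.get(str(nz), state.global_mean_d50) for nz in records["nozzle_id"]
    ]
    unseen = sorted({str(nz) for nz in records["nozzle_id"] if str(nz) not in state.nozzle_lookup})
    if unseen:
        log.info("nozzles unseen in training use the global mean: %s", ", ".join(unseen))
    return pd.Series(values, index=records.index, name=NOZZLE_COLUMN)


def build_features(
    records: pd.DataFrame, state: EncoderState, scale: bool = True
) -> pd.DataFrame:
    """Compose composition + nozzle column(s) + min-max scaling, in the
    encoder's fixed column order."""
    matrix = encode_composition(records, state)
    if state.use_target_encoding:
        matrix[NOZZLE_COLUMN] = encode_nozzles(records, state)
    if state.include_orifice_diameter:
        missing = sorted(
            {str(nz) for nz in records["nozzle_id"] if str(nz) not in state.orifice_diameters}
        )
        if missing:
            raise ValueError(f"orifice diameter unknown for nozzles: {', '.join(missing)}")
        matrix[ORIFICE_COLUMN] = [
            state.orifice_diameters[str(nz)] for nz in records["nozzle_id"]
        ]
    matrix = matrix[state.feature_columns]
    if scale and state.minmax:
        matrix = apply_minmax(matrix, state.minmax)
    return matrix


class SprayFeatureEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping the full encoding stack.

    Parameters
    ----------
    smoothing_k, smoothing_f
        Shift and scale of the logistic shrinkage weight in the nozzle
        target encoding (defaults k=1, f=3).
    use_target_encoding
        Include the smoothed nozzle encoding column.
    include_orifice_diameter
        Include a nozzle orifice diameter column (requires
        ``orifice_diameters``); may be combined with the target encoding
        or used instead of it.
    orifice_diameters
        Mapping nozzle_id -> orifice diameter (mm).
    scale
        Apply min-max scaling fitted on the training rows.

    ``fit`` expects the raw record frame; D50 is taken from ``y`` if given,
    else from the frame's ``d50`` column (needed only when target encoding
    is on).
    """

    def __init__(
        self,
        smoothing_k: int = 1,
        smoothing_f: float = 3.0,
        use_target_encoding: bool = True,
        include_orifice_diameter: bool = False,
        orifice_diameters: dict[str, float] | None = None,
        scale: bool = True,
    ):
        self.smoothing_k = smoothing_k
        self.smoothing_f = smoothing_f
        self.use_target_encoding = use_target_encoding
        self.include_orifice_diameter = include_orifice_diameter
        self.orifice_diameters = orifice_diameters
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None) -> "SprayFeatureEncoder":
        state = EncoderState(
            smoothing_k=self.smoothing_k,
            smoothing_f=self.smoothing_f,
            use_target_encoding=self.use_target_encoding,
            include_orifice_diameter=self.include_orifice_diameter,
            orifice_diameters=dict(self.orifice_diameters or {}),
        )
        state.polymer_columns = sorted(
            {
                schema.polymer_column(str(p))
                for p in X["polymer_type"].unique()
                if p != "None"
            }
        )
        state.solvent_columns = sorted(
            c
            for c in X.columns
            if c.startswith(SOLVENT_PREFIX) and (X[c].astype(float) != 0).any()
        )
        if self.use_target_encoding:
            train = X if y is None else X.assign(d50=np.asarray(y, dtype=float))
            state.nozzle_lookup, state.global_mean_d50 = fit_target_encoding(
                train, self.smoothing_k, self.smoothing_f
            )
        if self.scale:
            unscaled = build_features(X, state, scale=False)
            state.minmax = fit_minmax(unscaled)
        self.state_ = state
        self.feature_names_out_ = list(state.feature_columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "state_")
        return build_features(X, self.state_, scale=self.scale)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "state_")
        return np.asarray(self.feature_names_out_, dtype=object)
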