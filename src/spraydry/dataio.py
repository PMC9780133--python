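"""Dataset CSV I/O and run configuration.

The interchange format is a flat CSV with a versioned comment header.
Solvent columns are detected by the ``solvent_`` prefix. Hard invariants
(solvent fractions summing to 100, positive D50) reject rows with
row-numbered messages; soft range violations only warn — historical data
legitimately strays outside the documented envelope.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import schema
from .modeling import FAMILIES

log = logging.getLogger("spraydry")

_HEADER = f"# spraydry dataset schema={schema.SCHEMA_VERSION}"


def write_dataset(frame: pd.DataFrame, path) -> None:
    cols = [c for c in schema.dataset_columns() if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    buf = _io.StringIO()
    buf.write(_HEADER + "\n")
    frame[cols + extra].to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_dataset(path) -> pd.DataFrame:
    """Parse and validate a dataset CSV.

    Raises on missing mandatory columns or rows violating hard invariants;
    emits warnings for values outside the documented attribute ranges.
    """
    # keep_default_na: "None" is a real polymer-type level, not missing data
    frame = pd.read_csv(path, comment="#", keep_default_na=False, na_values=[""])
    missing = [c for c in schema.MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    solvent_cols = [c for c in frame.columns if c.startswith(schema.SOLVENT_PREFIX)]
    if not solvent_cols:
        raise ValueError("no solvent_* columns found")
    numeric = [*schema.FORMULATION_NUMERIC, *schema.PROCESS_PARAMS, *solvent_cols] + (
        ["d50"] if "d50" in frame.columns else []
    )
    for col in numeric:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} has unparseable numeric values: {exc}") from exc
    if "clipped" in frame.columns:
        frame["clipped"] = frame["clipped"].map(
            {"True": True, "False": False, True: True, False: False}
        )

    errors = []
    for i, row in frame.iterrows():
        if not str(row["api_id"]).strip():
            errors.append(f"row {i}: empty api_id")
            continue
        rec = schema.SprayRecord(
            api_id=str(row["api_id"]),
            polymer_type=str(row["polymer_type"]),
            nozzle_id=str(row["nozzle_id"]),
            dryer_scale=str(row["dryer_scale"]),
            active_loading=float(row["active_loading"]),
            polymer_loading=float(row["polymer_loading"]),
            solids_content=float(row["solids_content"]),
            solvent_fractions={c: float(row[c]) for c in solvent_cols},
            inlet_temp=float(row["inlet_temp"]),
            outlet_temp=float(row["outlet_temp"]),
            drying_gas_flow=float(row["drying_gas_flow"]),
            solution_to_gas_ratio=float(row["solution_to_gas_ratio"]),
            atomization_pressure=float(row["atomization_pressure"]),
            d50=float(row["d50"]) if "d50" in frame.columns and pd.notna(row["d50"]) else None,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                rec.validate(row=i)
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("rejected rows:\n" + "\n".join(errors))
    return frame


@dataclass
class RunConfig:
    """Flat configuration for the end-to-end pipeline.

    Desk-scale evolutionary defaults (population 30, tournament 8, 120
    iterations) replace the reference-scale 200/40/800, which remain
    available by configuration.
    """

    seed: int = 0
    # encoding
    smoothing_k: int = 1
    smoothing_f: float = 3.0
    use_target_encoding: bool = True
    include_orifice_diameter: bool = False
    # splitting
    test_fraction: float = 0.25
    n_clusters: int = 4
    # evolutionary search (empty list = train with optimized defaults)
    evolve_families: list = field(default_factory=list)
    population: int = 30
    tournament: int = 8
    iterations: int = 120
    # ensemble membership
    ensemble: list = field(default_factory=lambda: ["pls", "svr"])
    # inversion
    inversion_budget: int = 200
    n_imputation: int = 20
    # logging
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.smoothing_k < 0 or self.smoothing_f <= 0:
            raise ValueError("smoothing requires k >= 0 and f > 0")
        if self.population < 2 or self.tournament < 1 or self.iterations < 1:
            raise ValueError("evolution budget must be positive (population >= 2)")
        if self.inversion_budget < 10:
            raise ValueError("inversion_budget must be >= 10")
        unknown = [f for f in [*self.evolve_families, *self.ensemble] if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown model families: {', '.join(unknown)}")
        if not self.ensemble:
            raise ValueError("ensemble must name at least one member family")

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        config = cls(**data)
        config.validate()
        return config

    def save(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
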