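"""Dataset schema for spray-dried dispersion (SDD) records.

A *spray record* is one spray-drying lot: the formulation (drug loading,
polymer, solvent system, solids content), the process parameters (dryer
temperatures, drying-gas flow, solution-to-gas ratio, atomization pressure),
the atomizer nozzle and dryer scale, and — when measured — the volumetric
median particle size D50 of the dried powder, in microns.

Attribute ranges below are the envelope of the historical development data
this kind of model is built on; values outside them are suspicious but not
impossible, so range checks emit warnings rather than errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

log = logging.getLogger("spraydry")

SCHEMA_VERSION = "1"

#: Dryer scales: PSD-1 (pilot, ~100 kg/hr drying gas), PSD-2 (production, ~450 kg/hr).
SCALES = ("PSD-1", "PSD-2")

#: Polymer types seen in SDD development ("None" = no polymer / pure API spray).
POLYMER_TYPES = (
    "HPMC E3",
    "HPMCAS H",
    "HPMCAS L",
    "HPMCAS M",
    "HPMC-P",
    "PVP VA64",
    "Eudragit L100",
    "CAP",
    "None",
)

#: Spray solvents (wt% of the solvent system).
SOLVENT_TYPES = ("Acetone", "DCM", "Methanol", "THF", "Water")

SOLVENT_PREFIX = "solvent_"
POLYMER_PREFIX = "polymer_"


def solvent_column(name: str) -> str:
    return SOLVENT_PREFIX + name.lower().replace(" ", "_")


def polymer_column(name: str) -> str:
    return POLYMER_PREFIX + name.lower().replace(" ", "_").replace("-", "_")


#: Validation envelope per attribute: (lo, hi, units).
RANGES: dict[str, tuple[float, float, str]] = {
    "active_loading": (5.0, 100.0, "wt% dry basis"),
    "polymer_loading": (0.0, 19.5, "wt% in solution"),
    "solids_content": (0.6, 30.0, "wt%"),
    "inlet_temp": (52.5, 180.0, "degC"),
    "outlet_temp": (9.0, 66.8, "degC"),
    "drying_gas_flow": (500.0, 8500.0, "g/min"),
    "solution_to_gas_ratio": (0.019, 0.27, "-"),
    "atomization_pressure": (0.14, 7.03, "MPa"),
    "d50": (8.0, 104.0, "um"),
}

#: Output (D50) envelope, microns.
D50_RANGE = (8.0, 104.0)

#: Process parameters in canonical order — the searchable inputs at inversion time.
PROCESS_PARAMS = (
    "inlet_temp",
    "outlet_temp",
    "drying_gas_flow",
    "solution_to_gas_ratio",
    "atomization_pressure",
)

#: Numeric formulation attributes carried through as model features.
FORMULATION_NUMERIC = ("active_loading", "polymer_loading", "solids_content")

#: Categorical columns.
CATEGORICAL = ("api_id", "polymer_type", "nozzle_id", "dryer_scale")

#: Mandatory CSV columns (solvent columns are detected by prefix).
MANDATORY_COLUMNS = (
    "api_id",
    "polymer_type",
    "nozzle_id",
    "dryer_scale",
    *FORMULATION_NUMERIC,
    *PROCESS_PARAMS,
)

SOLVENT_SUM_TOL = 0.5


@dataclass
class SprayRecord:
    """One spray lot. ``d50`` is None for records awaiting measurement."""

    api_id: str
    polymer_type: str
    nozzle_id: str
    dryer_scale: str
    active_loading: float
    polymer_loading: float
    solids_content: float
    solvent_fractions: dict[str, float] = field(default_factory=dict)
    inlet_temp: float = float("nan")
    outlet_temp: float = float("nan")
    drying_gas_flow: float = float("nan")
    solution_to_gas_ratio: float = float("nan")
    atomization_pressure: float = float("nan")
    d50: float | None = None

    def validate(self, row: int | None = None) -> None:
        """Enforce hard invariants; warn on soft (range) violations.

        Hard: solvent fractions sum to 100 +- 0.5 with each in [0, 100];
        d50 > 0 when present; known dryer scale. Soft: attribute values
        inside the documented envelope.
        """
        where = f" (row {row})" if row is not None else ""
        if self.dryer_scale not in SCALES:
            raise ValueError(f"unknown dryer_scale {self.dryer_scale!r}{where}")
        total = sum(self.solvent_fractions.values())
        if abs(total - 100.0) > SOLVENT_SUM_TOL:
            raise ValueError(
                f"solvent fractions sum to {total:.2f}, expected 100 +- "
                f"{SOLVENT_SUM_TOL}{where}"
            )
        for name, frac in self.solvent_fractions.items():
            if not 0.0 <= frac <= 100.0:
                raise ValueError(f"solvent {name!r} fraction {frac} outside [0, 100]{where}")
        if self.d50 is not None and not self.d50 > 0:
            raise ValueError(f"d50 must be positive, got {self.d50}{where}")
        for attr, (lo, hi, units) in RANGES.items():
            value = getattr(self, attr, None)
            if value is None:
                continue
            if value == value and not lo <= value <= hi:  # NaN-safe
                warnings.warn(
                    f"{attr}={value:g} outside documented range [{lo:g}, {hi:g}] "
                    f"{units}{where}",
                    UserWarning,
                    stacklevel=2,
                )


def dataset_columns(solvents=SOLVENT_TYPES) -> list[str]:
    """Canonical CSV column order for a dataset."""
    return [
        "api_id",
        "polymer_type",
        "nozzle_id",
        "dryer_scale",
        *FORMULATION_NUMERIC,
        *[solvent_column(s) for s in solvents],
        *PROCESS_PARAMS,
        "d50",
    ]
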