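"""Seeded synthetic spray-drying datasets.

Historical SDD development data is proprietary, so this module generates
datasets with the statistical and mechanistic structure the modeling and
inversion stages assume: multiple APIs whose sprays share formulation
chemistry, two dryer scales with distinct drying-gas flow regimes, a pool of
pressure nozzles with size-dependent offsets, and a ground-truth D50 law with
the directional trends known from atomization physics — D50 falls with
atomization pressure, rises with solution-to-gas ratio, and scales with the
cube root of solids content (shrinking-sphere particle formation).

The generative law is a test harness with known signs and exponents, not a
physical droplet/drying model:

    D50 = base * nozzle_factor * scale_factor * api_effect
          * ratio^a * pressure^(-b) * solids^(1/3) * (1 + d * polymer_loading)

multiplied by lognormal noise with a configurable coefficient of variation
and clipped to the documented D50 envelope (clipped rows are flagged).

Sprays are organised as *campaigns*: within one API, each (nozzle, scale)
pair holds the spray solution and solution-to-gas ratio fixed while
atomization pressure and dryer conditions vary — the way a pressure scan is
actually run at the dryer. Within such a stratum the noise-free D50 is
therefore strictly monotone in pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .schema import SOLVENT_TYPES, solvent_column

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "true_d50",
    "write_ground_truth",
    "read_ground_truth",
]


def _default_envelope() -> dict[str, tuple[float, float]]:
    return {attr: (lo, hi) for attr, (lo, hi, _) in schema.RANGES.items()}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give ~500 sprays over 40 APIs at 10% relative noise — a
    desk-scale analogue of a multi-year historical development dataset.
    """

    n_apis: int = 40
    sprays_per_api: tuple[int, int] = (8, 16)
    n_nozzles: int = 30
    scale_mix: float = 0.25  # fraction of PSD-2 campaigns
    noise_cv: float = 0.10  # CV of multiplicative lognormal noise on D50
    seed: int = 0
    range_envelope: dict[str, tuple[float, float]] = field(default_factory=_default_envelope)

    def validate(self) -> None:
        if self.n_apis < 2:
            raise ValueError("n_apis must be >= 2")
        lo, hi = self.sprays_per_api
        if not (1 <= lo <= hi):
            raise ValueError("sprays_per_api must satisfy 1 <= lo <= hi")
        if self.n_nozzles < 1:
            raise ValueError("n_nozzles must be >= 1")
        if not 0.0 <= self.scale_mix <= 1.0:
            raise ValueError("scale_mix must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for attr, (lo, hi) in self.range_envelope.items():
            if lo >= hi:
                raise ValueError(f"range_envelope for {attr!r} has lo >= hi ({lo} >= {hi})")


@dataclass
class GroundTruth:
    """Parameters of the generative D50 law, kept alongside each dataset so
    tests and inversion round-trips have a forward oracle."""

    base: float = 40.0
    nozzle_size_factor: dict[str, float] = field(default_factory=dict)
    scale_factor: dict[str, float] = field(default_factory=lambda: {"PSD-1": 1.0, "PSD-2": 1.15})
    #: (a_ratio, b_pressure, c_solids, d_polymer); c_solids = 1/3 is the
    #: shrinking-sphere solids dependence.
    exponents: tuple[float, float, float, float] = (0.40, 0.45, 1.0 / 3.0, 0.012)
    api_effect: dict[str, float] = field(default_factory=dict)
    #: Per-solvent viscosity-like multiplier, fraction-weighted over the
    #: solvent system: more viscous systems (aqueous) atomize into larger
    #: droplets, volatile organics into smaller ones.
    solvent_factor: dict[str, float] = field(
        default_factory=lambda: {
            "Acetone": 0.90, "DCM": 0.90, "Methanol": 1.05, "THF": 1.05, "Water": 1.30,
        }
    )

    def solvent_multiplier(self, fractions: dict[str, float]) -> float:
        """Fraction-weighted solvent-system multiplier (fractions in wt%)."""
        total = sum(fractions.values())
        if total <= 0:
            return 1.0
        return sum(
            self.solvent_factor.get(name, 1.0) * frac for name, frac in fractions.items()
        ) / total

    def law(
        self, ratio, pressure, solids, polymer_loading, nozzle_factor, scale_f, api_eff,
        solvent_mult=1.0,
    ):
        """Noise-free D50 (um); vectorized over numpy arrays."""
        a, b, c, d = self.exponents
        return (
            self.base
            * np.asarray(nozzle_factor)
            * np.asarray(scale_f)
            * np.asarray(api_eff)
            * np.asarray(solvent_mult)
            * np.asarray(ratio) ** a
            * np.asarray(pressure) ** (-b)
            * np.asarray(solids) ** c
            * (1.0 + d * np.asarray(polymer_loading))
        )


_REQUIRED_FIELDS = (
    "nozzle_id",
    "dryer_scale",
    "solution_to_gas_ratio",
    "atomization_pressure",
    "solids_content",
    "polymer_loading",
)


def true_d50(record, truth: GroundTruth) -> float:
    """Noise-free D50 of one record under the generative law.

    ``record`` is any mapping / pandas row / SprayRecord with the process and
    formulation fields. Unknown nozzles, scales or APIs take multiplier 1.
    """
    get = (lambda k: getattr(record, k, None)) if not hasattr(record, "get") else record.get
    values = {}
    for name in _REQUIRED_FIELDS:
        v = get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"record is missing field {name!r}")
        values[name] = v
    api = get("api_id")
    fractions = {}
    for name in truth.solvent_factor:
        frac = get(solvent_column(name))
        if frac is not None and frac == frac:
            fractions[name] = float(frac)
    return float(
        truth.law(
            values["solution_to_gas_ratio"],
            values["atomization_pressure"],
            values["solids_content"],
            values["polymer_loading"],
            truth.nozzle_size_factor.get(values["nozzle_id"], 1.0),
            truth.scale_factor.get(values["dryer_scale"], 1.0),
            truth.api_effect.get(api, 1.0) if api is not None else 1.0,
            truth.solvent_multiplier(fractions),
        )
    )


def _window(envelope, attr, lo, hi):
    """Design sampling window intersected with the configured envelope."""
    elo, ehi = envelope[attr]
    lo, hi = max(lo, elo), min(hi, ehi)
    if lo >= hi:
        raise ValueError(f"range_envelope for {attr!r} excludes the sampling window")
    return lo, hi


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a seeded synthetic dataset.

    Returns ``(frame, truth)`` where ``frame`` follows the canonical dataset
    schema plus a boolean ``clipped`` column, and ``truth`` holds the
    generative parameters (the forward oracle for tests and inversion
    round-trips). Identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    env = config.range_envelope

    # Nozzle pool: PSD-2 campaigns run larger nozzles at higher gas flow.
    n2 = max(1, int(round(config.n_nozzles * config.scale_mix))) if config.scale_mix > 0 else 0
    n2 = min(n2, config.n_nozzles - 1) if config.scale_mix < 1 else config.n_nozzles
    nozzle_ids = [f"N{i:03d}" for i in range(config.n_nozzles)]
    psd2_nozzles = nozzle_ids[config.n_nozzles - n2 :]
    psd1_nozzles = nozzle_ids[: config.n_nozzles - n2] or nozzle_ids
    # Within a scale, nozzle idiosyncrasy beyond what flow regime explains is
    # modest; the dominant nozzle effect is the scale-level size step.
    factors = {}
    for nz in nozzle_ids:
        f = float(np.clip(rng.lognormal(0.0, 0.05), 0.88, 1.12))
        if nz in psd2_nozzles:
            f *= 1.20
        factors[nz] = round(f, 6)

    truth = GroundTruth(nozzle_size_factor=factors)
    truth.api_effect = {
        f"API-{i:03d}": round(float(np.clip(rng.lognormal(0.0, 0.06), 0.85, 1.18)), 6)
        for i in range(config.n_apis)
    }

    solids_w = _window(env, "solids_content", 8.0, 28.0)
    active_w = _window(env, "active_loading", 20.0, 90.0)
    ratio_w = _window(env, "solution_to_gas_ratio", 0.03, 0.20)
    press_w = _window(env, "atomization_pressure", 0.7, 4.0)
    inlet_w = _window(env, "inlet_temp", 80.0, 160.0)
    outlet_w = _window(env, "outlet_temp", 25.0, 55.0)
    flow1_w = _window(env, "drying_gas_flow", 800.0, 2400.0)
    flow2_w = _window(env, "drying_gas_flow", 2500.0, 8500.0)
    d50_lo, d50_hi = env["d50"]
    poly_hi = env["polymer_loading"][1]

    polymers = [p for p in schema.POLYMER_TYPES if p != "None"]
    rows = []
    for i, api in enumerate(sorted(truth.api_effect)):
        # Formulation chemistry is fixed within an API and drawn from the
        # standard levels formulators actually use (round-numbered loadings
        # and solvent splits shared across programs), so composition columns
        # describe chemistry rather than fingerprinting individual APIs.
        # Workhorse chemistry dominates: HPMCAS grades and PVP VA64 carry most
        # programs, acetone/methanol are the usual primary solvents.
        polymer_p = {
            "HPMCAS M": 0.25, "HPMCAS H": 0.15, "HPMCAS L": 0.15, "PVP VA64": 0.15,
            "HPMC E3": 0.10, "HPMC-P": 0.08, "Eudragit L100": 0.06, "CAP": 0.06,
        }
        polymer = (
            str(rng.choice(list(polymer_p), p=list(polymer_p.values())))
            if rng.random() > 0.05
            else "None"
        )
        solids = float(np.round(rng.uniform(*solids_w)))
        solids = float(np.clip(solids, *solids_w))
        active = (
            100.0
            if polymer == "None"
            else float(np.clip(5.0 * np.round(rng.uniform(*active_w) / 5.0), *active_w))
        )
        poly_load = min(solids * (1.0 - active / 100.0), poly_hi)
        # Water never carries the system — these APIs are poorly water-soluble
        # by definition — but is a common minor co-solvent.
        n_solv = 1 if rng.random() < 0.4 else 2
        primary_p = {"Acetone": 0.50, "Methanol": 0.25, "DCM": 0.15, "THF": 0.10}
        primary = str(rng.choice(list(primary_p), p=list(primary_p.values())))
        if n_solv == 1:
            solvents, fracs = [primary], [100.0]
        else:
            minor_pool = [s for s in SOLVENT_TYPES if s != primary]
            w = np.array([0.4 if s == "Water" else 0.2 for s in minor_pool])
            minor = str(rng.choice(minor_pool, p=w / w.sum()))
            main = float(rng.choice([60.0, 70.0, 80.0, 90.0, 95.0]))
            solvents, fracs = [primary, minor], [main, 100.0 - main]

        n_sprays = int(rng.integers(config.sprays_per_api[0], config.sprays_per_api[1] + 1))
        n_campaigns = int(rng.integers(2, min(4, n_sprays) + 1))
        sizes = np.full(n_campaigns, n_sprays // n_campaigns)
        sizes[: n_sprays % n_campaigns] += 1
        campaign_ratio: dict[tuple[str, str], float] = {}
        for size in sizes:
            on_psd2 = rng.random() < config.scale_mix
            scale = "PSD-2" if on_psd2 else "PSD-1"
            pool = psd2_nozzles if on_psd2 and psd2_nozzles else psd1_nozzles
            nozzle = pool[rng.integers(len(pool))]
            # Ratio and solution are fixed within a campaign; pressure varies.
            # Re-drawing the same (nozzle, scale) pair for an API reuses the
            # earlier ratio, so each stratum has a single solution setting.
            lr = np.log(ratio_w)
            ratio = campaign_ratio.setdefault(
                (nozzle, scale), float(np.exp(rng.uniform(lr[0], lr[1])))
            )
            flow_w = flow2_w if on_psd2 else flow1_w
            for _ in range(int(size)):
                lp = np.log(press_w)
                pressure = float(np.exp(rng.uniform(lp[0], lp[1])))
                inlet = float(rng.uniform(*inlet_w))
                outlet = float(rng.uniform(*outlet_w))
                flow = float(rng.uniform(*flow_w))
                row = {
                    "api_id": api,
                    "polymer_type": polymer,
                    "nozzle_id": nozzle,
                    "dryer_scale": scale,
                    "active_loading": round(active, 4),
                    "polymer_loading": round(poly_load, 4),
                    "solids_content": round(solids, 4),
                    **{solvent_column(s): 0.0 for s in SOLVENT_TYPES},
                    "inlet_temp": round(inlet, 4),
                    "outlet_temp": round(outlet, 4),
                    "drying_gas_flow": round(flow, 4),
                    "solution_to_gas_ratio": round(ratio, 6),
                    "atomization_pressure": round(pressure, 6),
                }
                for s, fr in zip(solvents, fracs):
                    row[solvent_column(s)] = round(fr, 4)
                rows.append(row)

    frame = pd.DataFrame(rows, columns=schema.dataset_columns()[:-1])
    clean = frame.apply(lambda r: true_d50(r, truth), axis=1).to_numpy()
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(frame))
    else:
        noise = np.ones(len(frame))
    noisy = clean * noise
    d50 = np.clip(noisy, d50_lo, d50_hi)
    frame["d50"] = d50
    frame["clipped"] = (noisy < d50_lo) | (noisy > d50_hi)
    return frame, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize a GroundTruth as a flat key=value sidecar file."""
    lines = [f"base={truth.base!r}"]
    a, b, c, d = truth.exponents
    lines += [f"a_ratio={a!r}", f"b_pressure={b!r}", f"c_solids={c!r}", f"d_polymer={d!r}"]
    for name, val in sorted(truth.nozzle_size_factor.items()):
        lines.append(f"nozzle_factor.{name}={val!r}")
    for name, val in sorted(truth.scale_factor.items()):
        lines.append(f"scale_factor.{name}={val!r}")
    for name, val in sorted(truth.solvent_factor.items()):
        lines.append(f"solvent_factor.{name}={val!r}")
    for name, val in sorted(truth.api_effect.items()):
        lines.append(f"api_effect.{name}={val!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path) -> GroundTruth:
    flat: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        flat[key.strip()] = float(value)
    truth = GroundTruth(
        base=flat.pop("base"),
        exponents=(
            flat.pop("a_ratio"),
            flat.pop("b_pressure"),
            flat.pop("c_solids"),
            flat.pop("d_polymer"),
        ),
        scale_factor={},
        solvent_factor={},
    )
    for key, value in flat.items():
        group, _, name = key.partition(".")
        target = {
            "nozzle_factor": truth.nozzle_size_factor,
            "scale_factor": truth.scale_factor,
            "api_effect": truth.api_effect,
            "solvent_factor": truth.solvent_factor,
        }[group]
        target[name] = value
    return truth
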