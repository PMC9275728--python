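"""Ocean environments and swim-bladder gas properties.

All quantities are strict SI internally (Pa, kg/m^3, Pa.s, N/m, m/s, m^2/s).
Unit conversion happens only at I/O boundaries: the shipped fixture file and
user-supplied property tables carry their own unit conventions.

The five study environments are two surface environments (warm 20.0 degC and
cold 1.5 degC) and three cold deep-water environments at 1000 m, 2000 m and
3500 m depth, all at salinity 35.0 g/kg, each with nitrogen and oxygen gas
parameters (the dominant swim-bladder gases).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

__all__ = [
    "Environment",
    "GasProperties",
    "PropertyProfile",
    "load_fixture_environments",
    "read_property_table",
    "write_property_table",
    "interpolate_profile",
    "laplace_gas_pressure",
    "PROFILE_COLUMNS",
]

GASES = ("N2", "O2")

#: canonical column order of a property-table CSV (per-gas columns follow)
PROFILE_COLUMNS = [
    "depth_m",
    "temperature_C",
    "salinity_g_kg",
    "pressure_Pa",
    "density_kg_m3",
    "viscosity_Pa_s",
    "surface_tension_N_m",
    "sound_speed_m_s",
]


@dataclass(frozen=True)
class Environment:
    """One water-side parameter set (SI units throughout)."""

    name: str
    depth_m: float
    temperature_C: float
    salinity_g_kg: float
    pressure_Pa: float
    density_kg_m3: float
    viscosity_Pa_s: float
    surface_tension_N_m: float
    sound_speed_m_s: float

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth_m}")
        for field in (
            "pressure_Pa",
            "density_kg_m3",
            "viscosity_Pa_s",
            "sound_speed_m_s",
        ):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(f"{field} must be > 0, got {value}")
        # tau = 0 is the admissible zero-surface-tension limit
        if self.surface_tension_N_m < 0:
            raise ValueError("surface tension must be >= 0")


@dataclass(frozen=True)
class GasProperties:
    """Bubble-gas parameters: specific-heat ratio and thermal diffusivity."""

    gas: str
    gamma: float
    thermal_diffusivity_m2_s: float

    def __post_init__(self) -> None:
        if not self.gamma > 1:
            raise ValueError(f"gamma must be > 1, got {self.gamma}")
        if not self.thermal_diffusivity_m2_s > 0:
            raise ValueError(
                f"thermal diffusivity must be > 0, got {self.thermal_diffusivity_m2_s}"
            )


def _fixture_records() -> list[dict]:
    text = (
        importlib.resources.files("deepbubble") / "data" / "table1.yaml"
    ).read_text(encoding="utf-8")
    return yaml.safe_load(text)["environments"]


def load_fixture_environments() -> list[tuple[Environment, GasProperties]]:
    """Load the five shipped environments paired with each of the two gases.

    Returns exactly 10 (Environment, GasProperties) pairs in fixture order
    (environment-major, N2 before O2), with values converted to SI:
    MPa -> Pa, mPa.s -> Pa.s, mN/m -> N/m, 1e-9 m^2/s -> m^2/s.
    """
    pairs: list[tuple[Environment, GasProperties]] = []
    for rec in _fixture_records():
        env = Environment(
            name=rec["name"],
            depth_m=float(rec["depth"]),
            temperature_C=float(rec["temperature"]),
            salinity_g_kg=float(rec["salinity"]),
            pressure_Pa=float(rec["ambient_pressure"]) * 1e6,
            density_kg_m3=float(rec["water_density"]),
            viscosity_Pa_s=float(rec["water_dynamic_viscosity"]) * 1e-3,
            surface_tension_N_m=float(rec["water_surface_tension"]) * 1e-3,
            sound_speed_m_s=float(rec["water_sound_speed"]),
        )
        for gas in GASES:
            g = rec["gases"][gas]
            pairs.append(
                (
                    env,
                    GasProperties(
                        gas=gas,
                        gamma=float(g["gamma"]),
                        thermal_diffusivity_m2_s=float(g["thermal_diffusivity"]) * 1e-9,
                    ),
                )
            )
    return pairs


def fixture_environment(name: str, gas: str) -> tuple[Environment, GasProperties]:
    """Look up one shipped (environment, gas) pair by name."""
    for env, g in load_fixture_environments():
        if env.name == name and g.gas == gas:
            return env, g
    names = sorted({e.name for e, _ in load_fixture_environments()})
    raise KeyError(f"no fixture {name!r}/{gas!r}; environments: {names}, gases: {GASES}")


def laplace_gas_pressure(env: Environment, R0: float, include_laplace: bool = True) -> float:
    """Equilibrium gas pressure inside a bubble of radius ``R0``.

    Uses the Laplace overpressure convention P_gas = P_liq + 2 tau / R0.
    The surface-tension term can be disabled; at swim-bladder radii
    (R0 >= 0.01 m) it is below 0.02% of the ambient pressure, so results
    are insensitive to the convention.
    """
    if not R0 > 0:
        raise ValueError(f"R0 must be > 0, got {R0}")
    if not include_laplace:
        return env.pressure_Pa
    return env.pressure_Pa + 2.0 * env.surface_tension_N_m / R0


class PropertyProfile:
    """Depth-resolved water and gas properties with cubic-spline interpolation.

    Wraps a table with one row per depth node (strictly increasing depth) and
    one column per property; queries between nodes use a cubic spline per
    column and reproduce node values exactly.
    """

    def __init__(self, frame: pd.DataFrame):
        if "depth_m" not in frame.columns:
            raise ValueError("profile table must have a depth_m column")
        missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"profile table missing columns: {missing}")
        self.gases = tuple(
            g for g in GASES
            if f"gamma_{g}" in frame.columns
            and f"thermal_diffusivity_{g}_m2_s" in frame.columns
        )
        if not self.gases:
            raise ValueError(
                "profile table must have gamma_<gas> and "
                "thermal_diffusivity_<gas>_m2_s columns for at least one gas"
            )
        depths = frame["depth_m"].to_numpy(dtype=float)
        if len(depths) < 2:
            raise ValueError("profile needs at least two depth nodes")
        if not np.all(np.diff(depths) > 0):
            raise ValueError("depth_m must be strictly increasing with no duplicates")
        for col in frame.columns:
            if col in ("depth_m", "temperature_C"):
                continue
            vals = frame[col].to_numpy(dtype=float)
            bad = np.nonzero(~(vals > 0))[0]
            if bad.size:
                raise ValueError(
                    f"column {col} must be strictly positive; offending row index {bad[0]}"
                )
        self.frame = frame.reset_index(drop=True)
        self.depths = depths
        # with only 2 nodes a cubic spline is ill-posed; fall back to linear
        kind = "not-a-knot" if len(depths) > 2 else ((1, 0.0), (1, 0.0))
        self._splines = {}
        self._log_columns = set()
        for col in self.frame.columns:
            if col == "depth_m":
                continue
            vals = self.frame[col].to_numpy(dtype=float)
            # thermal diffusivity spans two decades over a deep profile
            # (roughly inverse to pressure); splining its logarithm keeps the
            # interpolant positive and tracks the physical trend, where a
            # value-space cubic overshoots below zero
            if col.startswith("thermal_diffusivity_"):
                self._log_columns.add(col)
                vals = np.log(vals)
            self._splines[col] = CubicSpline(depths, vals, bc_type=kind)

    @property
    def depth_range(self) -> tuple[float, float]:
        return float(self.depths[0]), float(self.depths[-1])

    def __iter__(self) -> Iterator[float]:
        return iter(self.depths)


def read_property_table(path) -> PropertyProfile:
    """Read a property-vs-depth CSV (comma-separated, header row, '.' decimal,
    UTF-8) into a :class:`PropertyProfile`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return PropertyProfile(frame)


def write_property_table(profile: PropertyProfile, path) -> None:
    """Write a profile back to CSV in the canonical dialect."""
    profile.frame.to_csv(path, index=False, lineterminator="\n")


def interpolate_profile(
    profile: PropertyProfile, depth: float, gas: str = "N2"
) -> tuple[Environment, GasProperties]:
    """Cubic-spline interpolate all properties at ``depth`` (no extrapolation)."""
    lo, hi = profile.depth_range
    if not (lo <= depth <= hi):
        raise ValueError(f"depth {depth} outside profile range [{lo}, {hi}]")
    if gas not in profile.gases:
        raise KeyError(f"profile has no columns for gas {gas!r}; has {profile.gases}")

    def col(name: str) -> float:
        val = float(profile._splines[name](depth))
        return float(np.exp(val)) if name in profile._log_columns else val

    env = Environment(
        name=f"profile@{depth:g}m",
        depth_m=float(depth),
        temperature_C=col("temperature_C"),
        salinity_g_kg=col("salinity_g_kg"),
        pressure_Pa=col("pressure_Pa"),
        density_kg_m3=col("density_kg_m3"),
        viscosity_Pa_s=col("viscosity_Pa_s"),
        surface_tension_N_m=col("surface_tension_N_m"),
        sound_speed_m_s=col("sound_speed_m_s"),
    )
    gasp = GasProperties(
        gas=gas,
        gamma=col(f"gamma_{gas}"),
        thermal_diffusivity_m2_s=col(f"thermal_diffusivity_{gas}_m2_s"),
    )
    return env, gasp


def profile_from_environments(
    pairs: list[tuple[Environment, GasProperties]]
) -> PropertyProfile:
    """Build a profile table from (Environment, GasProperties) pairs.

    Pairs sharing a depth are merged into one row (one column set per gas).
    Depths must be unique per environment.
    """
    rows: dict[float, dict] = {}
    for env, gasp in pairs:
        row = rows.setdefault(
            env.depth_m,
            {
                "depth_m": env.depth_m,
                "temperature_C": env.temperature_C,
                "salinity_g_kg": env.salinity_g_kg,
                "pressure_Pa": env.pressure_Pa,
                "density_kg_m3": env.density_kg_m3,
                "viscosity_Pa_s": env.viscosity_Pa_s,
                "surface_tension_N_m": env.surface_tension_N_m,
                "sound_speed_m_s": env.sound_speed_m_s,
            },
        )
        row[f"gamma_{gasp.gas}"] = gasp.gamma
        row[f"thermal_diffusivity_{gasp.gas}_m2_s"] = gasp.thermal_diffusivity_m2_s
    frame = pd.DataFrame([rows[d] for d in sorted(rows)])
    return PropertyProfile(frame)


def cold_depth_profile() -> PropertyProfile:
    """The constant-temperature (1.5 degC), constant-salinity (35 g/kg) depth
    profile through the cold fixture environments (0, 1000, 2000, 3500 m)."""
    pairs = [
        (env, gasp)
        for env, gasp in load_fixture_environments()
        if env.temperature_C == 1.5
    ]
    return profile_from_environments(pairs)


def with_surface_tension(env: Environment, tau: float) -> Environment:
    """Copy of ``env`` with the surface tension replaced (limit-case helper)."""
    return replace(env, surface_tension_N_m=tau)
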