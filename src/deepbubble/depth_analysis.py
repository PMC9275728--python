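"""Depth-resolved bubble acoustics along a water-property profile.

Given a property-vs-depth table (for the study conditions: constant 1.5 degC,
35 g/kg salinity, with the deep rows at 1000/2000/3500 m), these analyses
track how the resonance frequencies, the far-field-to-Minnaert ratio and the
radiated-power efficiency of a fixed-radius bubble change with depth.

The canonical comparison radius is R0 = 0.10 m: peak heights of the
normalized scattering cross-section retain a mild radius dependence through
thermal damping, and 0.10 m is the radius at which the fold-reduction factors
of the study conditions are quoted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bubble_core import BubbleSpec
from .environments import PropertyProfile, interpolate_profile
from .resonance_solvers import solve_far_field, solve_undamped
from . import bubble_core as bc

__all__ = [
    "DepthCurve",
    "CANONICAL_RADIUS_M",
    "frequency_vs_depth",
    "minnaert_ratio_vs_depth",
    "power_reduction_db",
]

#: radius used for the depth-comparison figures of the study conditions
CANONICAL_RADIUS_M = 0.10


@dataclass(frozen=True)
class DepthCurve:
    """One named quantity sampled on a strictly increasing depth grid."""

    quantity: str
    gas: str
    R0: float
    depths_m: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_m, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.shape != v.shape:
            raise ValueError("depth grid and values must have the same shape")
        if not np.all(np.diff(d) > 0):
            raise ValueError("depth grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in depth curve {self.quantity!r}")
        object.__setattr__(self, "depths_m", d)
        object.__setattr__(self, "values", v)


def _spec_at(profile: PropertyProfile, depth: float, gas: str, R0: float) -> BubbleSpec:
    env, gasp = interpolate_profile(profile, depth, gas)
    return BubbleSpec(R0=R0, env=env, gas=gasp)


def frequency_vs_depth(
    profile: PropertyProfile, gas: str, R0: float, depths
) -> tuple[DepthCurve, DepthCurve]:
    """Undamped (f_und) and far-field (f_sigma) frequencies at each depth."""
    depths = np.asarray(depths, dtype=float)
    f_und = np.empty_like(depths)
    f_sig = np.empty_like(depths)
    for i, d in enumerate(depths):
        spec = _spec_at(profile, d, gas, R0)
        f_und[i] = solve_undamped(spec)
        f_sig[i], _ = solve_far_field(spec)
    return (
        DepthCurve("f_und_Hz", gas, R0, depths, f_und),
        DepthCurve("f_sigma_Hz", gas, R0, depths, f_sig),
    )


def minnaert_ratio_vs_depth(
    profile: PropertyProfile, gas: str, R0: float, depths
) -> DepthCurve:
    """Ratio of the far-field resonant frequency to the Minnaert frequency."""
    depths = np.asarray(depths, dtype=float)
    ratio = np.empty_like(depths)
    for i, d in enumerate(depths):
        spec = _spec_at(profile, d, gas, R0)
        f_sigma, _ = solve_far_field(spec)
        ratio[i] = f_sigma / bc.minnaert_frequency(spec)
    return DepthCurve("f_sigma_over_f_M", gas, R0, depths, ratio)


def power_reduction_db(
    profile: PropertyProfile, gas: str, R0: float, depths
) -> DepthCurve:
    """Radiated-power loss at depth, 10 log10[sigma_s(d) / sigma_s(0)] in dB.

    sigma_s at each depth is the peak of the scattering cross-section at that
    depth's own far-field resonance (same R0, same gas); the reference is the
    profile's surface (0 m) entry, so the profile must start at the surface.
    Values are <= 0; more negative means a less efficient radiator.
    """
    lo, _ = profile.depth_range
    if lo != 0.0:
        raise ValueError("power reduction needs a surface (0 m) profile entry")
    depths = np.asarray(depths, dtype=float)
    _, surface_peak = solve_far_field(_spec_at(profile, 0.0, gas, R0))
    out = np.empty_like(depths)
    for i, d in enumerate(depths):
        _, peak = solve_far_field(_spec_at(profile, d, gas, R0))
        out[i] = 10.0 * math.log10(peak.sigma_s / surface_peak.sigma_s)
    return DepthCurve("power_reduction_dB", gas, R0, depths, out)
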