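"""Synthetic parameter sets for exercising the whole pipeline offline.

Three generators:

* ``table1_fixtures``  the ten shipped (environment, gas) pairs;
* ``perturbed_specs``  seeded random bubbles: log-uniform radii in
  [0.005, 0.25] m and +/-20% multiplicative perturbations of every water/gas
  property, for property-based tests across the physically plausible
  neighbourhood of the study conditions;
* ``limit_cases``      bubbles constructed to sit in closed-form limits
  (zero surface tension, isothermal X -> 0, adiabatic X -> infinity,
  incompressible-liquid eps -> 0).
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bubble_core import BubbleSpec
from .environments import (
    Environment,
    GasProperties,
    load_fixture_environments,
)

__all__ = ["table1_fixtures", "perturbed_specs", "limit_cases"]

_R0_RANGE = (0.005, 0.25)
_PERTURBATION = 0.20


def table1_fixtures() -> list[tuple[Environment, GasProperties]]:
    """The ten shipped (Environment, GasProperties) pairs."""
    return load_fixture_environments()


def perturbed_specs(seed: int, n: int) -> list[BubbleSpec]:
    """``n`` deterministic random bubbles around the shipped environments.

    Radii are log-uniform in [0.005, 0.25] m; each physical property of the
    base (environment, gas) pair is scaled by an independent uniform factor
    in [0.8, 1.2]. The same seed always yields the identical list.
    """
    if not n > 0:
        raise ValueError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed)
    base = table1_fixtures()
    specs: list[BubbleSpec] = []
    for i in range(n):
        env, gas = base[rng.integers(len(base))]
        lo, hi = np.log(_R0_RANGE)
        R0 = float(np.exp(rng.uniform(lo, hi)))

        def jitter() -> float:
            return float(rng.uniform(1.0 - _PERTURBATION, 1.0 + _PERTURBATION))

        env = replace(
            env,
            name=f"{env.name}_perturbed_{i}",
            pressure_Pa=env.pressure_Pa * jitter(),
            density_kg_m3=env.density_kg_m3 * jitter(),
            viscosity_Pa_s=env.viscosity_Pa_s * jitter(),
            surface_tension_N_m=env.surface_tension_N_m * jitter(),
            sound_speed_m_s=env.sound_speed_m_s * jitter(),
        )
        gas = replace(
            gas,
            gamma=gas.gamma * jitter(),
            thermal_diffusivity_m2_s=gas.thermal_diffusivity_m2_s * jitter(),
        )
        specs.append(BubbleSpec(R0=R0, env=env, gas=gas))
    return specs


def limit_cases() -> list[BubbleSpec]:
    """Bubbles sitting in closed-form limits, for exact-value tests.

    * ``minnaert_limit``: tau = 0, huge thermal diffusion ratio (adiabatic)
      and a huge sound speed (eps -> 0), so the far-field resonance collapses
      onto the Minnaert frequency.
    * ``isothermal_limit``: enormous thermal diffusivity forces X -> 0 and
      Re Gamma -> 1 at audio frequencies.
    * ``incompressible_limit``: huge sound speed makes the acoustic damping
      negligible.
    """
    envs = {e.name: (e, g) for e, g in table1_fixtures() if g.gas == "N2"}
    warm, n2 = envs["warm_surface"]

    minnaert = BubbleSpec(
        R0=0.05,
        env=replace(warm, name="minnaert_limit", surface_tension_N_m=0.0,
                    sound_speed_m_s=1e9),
        gas=replace(n2, thermal_diffusivity_m2_s=1e-18),  # X -> infinity
    )
    isothermal = BubbleSpec(
        R0=0.05,
        env=replace(warm, name="isothermal_limit"),
        gas=replace(n2, thermal_diffusivity_m2_s=1e6),  # X -> 0
    )
    incompressible = BubbleSpec(
        R0=0.05,
        env=replace(warm, name="incompressible_limit", sound_speed_m_s=1e9),
        gas=n2,
    )
    return [minnaert, isothermal, incompressible]
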