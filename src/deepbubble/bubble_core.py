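"""Frequency-dependent physics of a driven spherical gas bubble.

A swim bladder is modelled as a spherical bubble of equilibrium radius R0 in
water, driven at angular frequency omega. The linearized radial equation of
motion has a frequency-dependent stiffness K(omega) and damping beta(omega)
because (i) heat conduction between gas and water makes the effective
polytropic index a complex function Gamma(omega) interpolating between
isothermal (Gamma -> 1, small bubbles / low frequency) and adiabatic
(Gamma -> gamma) behaviour, and (ii) sound radiation loads the bubble wall
with the exact monopole impedance.

Quantities, all referenced to the full entrained liquid mass rho_liq * R0:

* ``omega0_squared``  3 Re Gamma P_gas / (rho R0^2) - 2 tau / (rho R0^3),
  the gas + surface-tension stiffness.
* ``stiffness``       K = omega0^2 + [eps^2/(1+eps^2)] omega^2 where
  eps = omega R0 / c; the second term is the pseudo-stiffness produced by the
  drop of the radiation (entrained-liquid) mass with frequency.
* ``damping``         beta = beta_th + beta_vis + beta_ac with
  beta_th = 3 P_gas Im Gamma / (2 rho R0^2 omega),
  beta_vis = 2 eta_s / (rho R0^2),
  beta_ac = (omega/2) eps / (1 + eps^2).
* ``scattering_cross_section``  sigma_s = 4 pi R0^2 / D with
  D = (omega0^2/omega^2 - 1 - 2 beta0 eps/omega)^2
    + (2 beta0/omega + (omega0^2/omega^2) eps)^2,
  where beta0 = beta_th + beta_vis is the NON-acoustic damping: radiation
  loss enters D exactly through the eps terms, and substituting the total
  beta would double-count it. D is algebraically identical to
  |K - omega^2 + 2 i beta omega|^2 (1+eps^2) / omega^4, i.e. this sigma_s is
  the exact linear response of the radiating monopole.

All operations take omega in rad/s; f = omega/(2 pi) only in reporting.
"""
from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

from .environments import Environment, GasProperties, laplace_gas_pressure

__all__ = [
    "BubbleSpec",
    "ThermalState",
    "DampingBreakdown",
    "ResponsePoint",
    "minnaert_omega",
    "minnaert_frequency",
    "complex_polytropic_index",
    "thermal_state",
    "omega0_squared",
    "stiffness",
    "damping",
    "scattering_cross_section",
]

TWO_PI = 2.0 * math.pi

# |z| beyond which tanh(z) is numerically 1 (z = (1+i) X / 2, so X/2 > 20)
_TANH_SATURATION_X = 40.0
# below this X, z/tanh(z) - 1 is evaluated by series to avoid cancellation
_SERIES_X = 2.0


@dataclass(frozen=True)
class BubbleSpec:
    """A bubble: equilibrium radius bound to an environment and a gas.

    ``P_gas`` (the equilibrium pressure of the enclosed gas, including the
    Laplace overpressure unless disabled) is derived once at construction.
    """

    R0: float
    env: Environment
    gas: GasProperties
    include_laplace: bool = True
    P_gas: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError(f"R0 must be > 0, got {self.R0}")
        object.__setattr__(
            self,
            "P_gas",
            laplace_gas_pressure(self.env, self.R0, self.include_laplace),
        )


@dataclass(frozen=True)
class ThermalState:
    """Thermal-diffusion state of the gas at one driving frequency."""

    omega: float
    l_th: float      # thermal diffusion length sqrt(D_p / (2 omega)), m
    X: float         # thermal diffusion ratio R0 / l_th
    Gamma: complex   # complex polytropic index


@dataclass(frozen=True)
class DampingBreakdown:
    """Damping decomposition at one driving frequency (all rad/s)."""

    beta_th: float
    beta_vis: float
    beta_ac: float

    @property
    def beta0(self) -> float:
        """Non-acoustic damping (enters the scattering denominator)."""
        return self.beta_th + self.beta_vis

    @property
    def beta(self) -> float:
        """Total damping beta0 + beta_ac."""
        return self.beta_th + self.beta_vis + self.beta_ac


@dataclass(frozen=True)
class ResponsePoint:
    """Sampled response quantities at one driving frequency."""

    omega: float
    epsilon: float        # dimensionless frequency omega R0 / c
    omega0_sq: float      # rad^2/s^2
    K: float              # stiffness, rad^2/s^2
    sigma_s: float        # scattering cross-section, m^2
    sigma_s_norm: float   # sigma_s / (4 pi R0^2)


def minnaert_omega(spec: BubbleSpec) -> float:
    """Closed-form angular frequency (1/R0) sqrt(3 gamma P_liq / rho_liq) of a
    large adiabatic bubble."""
    env = spec.env
    return math.sqrt(3.0 * spec.gas.gamma * env.pressure_Pa / env.density_kg_m3) / spec.R0


def minnaert_frequency(spec: BubbleSpec) -> float:
    """Minnaert frequency in Hz."""
    return minnaert_omega(spec) / TWO_PI


def complex_polytropic_index(gamma: float, X: float) -> complex:
    """Complex polytropic index Gamma(X) for specific-heat ratio ``gamma``.

    Gamma = gamma / (1 - {z/tanh(z) - 1} * 6 i (gamma-1) / X^2) with
    z = (1+i) X / 2. For X -> 0 (thermal diffusion much faster than the
    oscillation) Gamma -> 1 (isothermal); for X -> infinity Gamma -> gamma
    (adiabatic). Evaluation is cancellation-safe at small X (series) and
    overflow-safe at large X (tanh saturates to 1).
    """
    if not X > 0:
        raise ValueError(f"X must be > 0, got {X}")
    z = complex(0.5 * X, 0.5 * X)
    if X < _SERIES_X:
        t = _z_coth_z_minus_1_series(z)
    elif X > _TANH_SATURATION_X:
        t = z - 1.0
    else:
        t = z / cmath.tanh(z) - 1.0
    return gamma / (1.0 - t * (6j * (gamma - 1.0)) / (X * X))


def _z_coth_z_minus_1_series(z: complex) -> complex:
    """z/tanh(z) - 1 without the catastrophic cancellation of the direct form.

    Uses z cosh z - sinh z = sum_{k>=1} 2k z^(2k+1) / (2k+1)!, whose terms
    carry no sign cancellation, divided by sinh z. Accurate to full double
    precision for |z| of order 1 and below.
    """
    z2 = z * z
    term = z * z2 / 3.0  # k = 1
    total = term
    k = 1
    while abs(term) > 1e-18 * abs(total):
        # ratio of consecutive terms: z^2 (k+1) / (k (2k+2)(2k+3))
        k += 1
        term *= z2 * k / ((k - 1) * (2 * k) * (2 * k + 1))
        total += term
        if k > 60:  # pragma: no cover - |z| < sqrt(2) converges long before
            break
    return total / cmath.sinh(z)


def thermal_state(spec: BubbleSpec, omega: float) -> ThermalState:
    """Thermal diffusion length, diffusion ratio and polytropic index at
    driving frequency ``omega``."""
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    l_th = math.sqrt(spec.gas.thermal_diffusivity_m2_s / (2.0 * omega))
    X = spec.R0 / l_th
    return ThermalState(
        omega=omega, l_th=l_th, X=X, Gamma=complex_polytropic_index(spec.gas.gamma, X)
    )


def omega0_squared(spec: BubbleSpec, omega: float) -> float:
    """Gas + surface-tension stiffness over the liquid mass, rad^2/s^2."""
    ts = thermal_state(spec, omega)
    rho = spec.env.density_kg_m3
    R0 = spec.R0
    val = (
        3.0 * ts.Gamma.real * spec.P_gas / (rho * R0 * R0)
        - 2.0 * spec.env.surface_tension_N_m / (rho * R0 * R0 * R0)
    )
    if val <= 0:
        raise ValueError(
            "omega0^2 <= 0: surface tension dominates the gas stiffness; "
            "outside the model's validity range"
        )
    return val


def epsilon(spec: BubbleSpec, omega: float) -> float:
    """Dimensionless frequency omega R0 / c."""
    return omega * spec.R0 / spec.env.sound_speed_m_s


def stiffness(spec: BubbleSpec, omega: float) -> float:
    """Bubble stiffness K(omega) = omega0^2 + [eps^2/(1+eps^2)] omega^2."""
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    eps = epsilon(spec, omega)
    e2 = eps * eps
    return omega0_squared(spec, omega) + (e2 / (1.0 + e2)) * omega * omega


def damping(spec: BubbleSpec, omega: float) -> DampingBreakdown:
    """Thermal, viscous and acoustic damping factors at ``omega``."""
    ts = thermal_state(spec, omega)
    rho = spec.env.density_kg_m3
    R0sq = spec.R0 * spec.R0
    beta_th = 3.0 * spec.P_gas * ts.Gamma.imag / (2.0 * rho * R0sq * omega)
    beta_vis = 2.0 * spec.env.viscosity_Pa_s / (rho * R0sq)
    eps = epsilon(spec, omega)
    beta_ac = 0.5 * omega * eps / (1.0 + eps * eps)
    return DampingBreakdown(beta_th=beta_th, beta_vis=beta_vis, beta_ac=beta_ac)


def scattering_cross_section(spec: BubbleSpec, omega: float) -> ResponsePoint:
    """Scattering cross-section and companion response quantities at ``omega``.

    Only the non-acoustic damping beta0 appears explicitly; radiation loss is
    carried exactly by the eps terms of the denominator.
    """
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    w0sq = omega0_squared(spec, omega)
    b = damping(spec, omega)
    eps = epsilon(spec, omega)
    s = w0sq / (omega * omega)
    b0w = 2.0 * b.beta0 / omega
    den = (s - 1.0 - b0w * eps) ** 2 + (b0w + s * eps) ** 2
    area = 4.0 * math.pi * spec.R0 * spec.R0
    sigma = area / den
    return ResponsePoint(
        omega=omega,
        epsilon=eps,
        omega0_sq=w0sq,
        K=w0sq + (eps * eps / (1.0 + eps * eps)) * omega * omega,
        sigma_s=sigma,
        sigma_s_norm=sigma / area,
    )
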