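"""Resonance frequencies, quality factor and their ratios for a driven bubble.

Because stiffness K and damping beta depend on the driving frequency, each
resonance is defined implicitly:

* undamped frequency    omega_und solves omega = sqrt(K(omega));
* natural frequency     omega_nat solves omega^2 = K(omega) - beta(omega)^2
  (absent when the motion is overdamped);
* far-field resonance   omega_sigma maximizes the scattering cross-section
  sigma_s(omega) -- the frequency at which a driven bladder radiates sound to
  distant receivers most efficiently;
* quality factor        Q_f = omega_sigma / (2 beta(omega_sigma)) with the
  total damping.

Roots are bracketed around the Minnaert frequency (every studied resonance
lies within a few percent of it) and widened geometrically on failure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from scipy.optimize import brentq, minimize_scalar

from . import bubble_core as bc
from .bubble_core import BubbleSpec, ResponsePoint

__all__ = [
    "ResonanceSummary",
    "solve_undamped",
    "solve_natural",
    "solve_far_field",
    "quality_factor",
    "summarize",
    "damping_regime",
    "BracketError",
]

ROOT_RTOL = 1e-12
MAX_RTOL = 1e-10       # relative tolerance of the sigma_s maximizer
_BRACKET0 = (0.5, 2.0)  # initial bracket in units of omega_M
_BRACKET_MAX = (1e-2, 1e2)
_CRITICAL_BAND = 1e-9


class BracketError(RuntimeError):
    """A root or maximum could not be isolated inside the search bracket."""

    def __init__(self, message: str, curve: Optional[list] = None):
        super().__init__(message)
        self.curve = curve  # diagnostic (omega, g(omega)) samples


@dataclass(frozen=True)
class ResonanceSummary:
    """All resonance quantities for one bubble (frequencies in Hz)."""

    f_M: float
    f_und: float
    f_nat: Optional[float]   # None when overdamped (no natural oscillation)
    f_sigma: float
    Q_f: float
    beta_at_resonance: float  # total beta(omega_sigma), rad/s

    @property
    def ratio_sigma_und(self) -> float:
        """omega_sigma / omega_und; the normalized peak location f'."""
        return self.f_sigma / self.f_und

    @property
    def ratio_sigma_minnaert(self) -> float:
        return self.f_sigma / self.f_M


def _widening_brackets(omega_M: float):
    lo, hi = _BRACKET0
    while lo >= _BRACKET_MAX[0] and hi <= _BRACKET_MAX[1]:
        yield lo * omega_M, hi * omega_M
        lo *= 0.5
        hi *= 2.0


def _solve_root(g: Callable[[float], float], omega_M: float, what: str) -> Optional[float]:
    """Bracketed root of g; widens geometrically; checks the sign change."""
    for lo, hi in _widening_brackets(omega_M):
        glo, ghi = g(lo), g(hi)
        if glo == 0.0:
            return lo
        if ghi == 0.0:
            return hi
        if glo * ghi < 0.0:
            return brentq(g, lo, hi, rtol=ROOT_RTOL, xtol=1e-30 * omega_M + 1e-300)
    n = 200
    lo, hi = _BRACKET_MAX[0] * omega_M, _BRACKET_MAX[1] * omega_M
    curve = []
    for i in range(n + 1):
        w = lo * (hi / lo) ** (i / n)
        try:
            curve.append((w, g(w)))
        except ValueError:
            curve.append((w, math.nan))
    raise BracketError(f"no sign change found for {what} in bracket", curve=curve)


def solve_undamped(spec: BubbleSpec) -> float:
    """Undamped oscillation frequency f_und (Hz): root of sqrt(K(omega)) = omega."""
    omega_M = bc.minnaert_omega(spec)
    g = lambda w: math.sqrt(bc.stiffness(spec, w)) - w
    return _solve_root(g, omega_M, "undamped frequency") / bc.TWO_PI


def solve_natural(spec: BubbleSpec) -> Optional[float]:
    """Natural (unforced, damped) frequency f_nat (Hz).

    Solves omega^2 = K(omega) - beta(omega)^2. Returns ``None`` when the
    motion is overdamped at every candidate frequency (no natural
    oscillation) rather than raising.
    """
    omega_M = bc.minnaert_omega(spec)

    def g(w: float) -> float:
        beta = bc.damping(spec, w).beta
        return bc.stiffness(spec, w) - beta * beta - w * w

    try:
        return _solve_root(g, omega_M, "natural frequency") / bc.TWO_PI
    except BracketError as err:
        if err.curve is not None and all(
            (v < 0 or math.isnan(v)) for _, v in err.curve
        ):
            return None  # K - beta^2 < omega^2 everywhere: overdamped
        raise


def solve_far_field(spec: BubbleSpec) -> tuple[float, ResponsePoint]:
    """Far-field resonance: the frequency maximizing sigma_s.

    Returns (f_sigma in Hz, the ResponsePoint at the peak). The maximizer is
    seeded from omega_und with a [0.5, 2] bracket; if the maximum lands on a
    boundary, the bracket is widened once and then the solve fails loudly.
    """
    w_und = solve_undamped(spec) * bc.TWO_PI
    neg_log_sigma = lambda w: -math.log(bc.scattering_cross_section(spec, w).sigma_s)
    lo, hi = 0.5 * w_und, 2.0 * w_und
    for attempt in range(2):
        res = minimize_scalar(
            neg_log_sigma,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": MAX_RTOL * w_und},
        )
        w_peak = float(res.x)
        margin = 1e-6 * (hi - lo)
        if lo + margin < w_peak < hi - margin:
            return w_peak / bc.TWO_PI, bc.scattering_cross_section(spec, w_peak)
        lo, hi = lo * 0.1, hi * 10.0
    raise BracketError("sigma_s maximum pinned to the bracket boundary")


def quality_factor(spec: BubbleSpec) -> float:
    """Q_f = omega_sigma / (2 beta(omega_sigma)) with the total damping."""
    f_sigma, _ = solve_far_field(spec)
    w_sigma = f_sigma * bc.TWO_PI
    return w_sigma / (2.0 * bc.damping(spec, w_sigma).beta)


def summarize(spec: BubbleSpec) -> ResonanceSummary:
    """Solve every resonance for one bubble and collect the results."""
    f_und = solve_undamped(spec)
    f_nat = solve_natural(spec)
    f_sigma, _peak = solve_far_field(spec)
    w_sigma = f_sigma * bc.TWO_PI
    beta = bc.damping(spec, w_sigma).beta
    return ResonanceSummary(
        f_M=bc.minnaert_frequency(spec),
        f_und=f_und,
        f_nat=f_nat,
        f_sigma=f_sigma,
        Q_f=w_sigma / (2.0 * beta),
        beta_at_resonance=beta,
    )


def damping_regime(spec: BubbleSpec, omega: float) -> str:
    """Classify the response at ``omega``: 'underdamped' | 'critical' | 'overdamped'.

    The classification compares the total damping factor with the undamped
    angular frequency, beta(omega)/omega_und against 1.
    """
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    w_und = solve_undamped(spec) * bc.TWO_PI
    ratio = bc.damping(spec, omega).beta / w_und
    if abs(ratio - 1.0) <= _CRITICAL_BAND:
        return "critical"
    return "underdamped" if ratio < 1.0 else "overdamped"
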