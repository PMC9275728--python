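# Methods

## Physical model

The swim bladder is idealized as a spherical gas bubble of equilibrium radius
R₀ pulsating radially in an unbounded liquid, in the linear (small-amplitude)
regime with zero mean flow. The model resolves three couplings that the
classic Minnaert formula ignores:

1. **Thermal behaviour of the gas.** Compression heat diffuses between gas
   and liquid over the thermal diffusion length l_th = √(D_p/2ω). The ratio
   X = R₀/l_th controls a continuous transition from isothermal (X → 0) to
   adiabatic (X → ∞) compression, encoded in the complex polytropic index

       Γ(ω) = γ / (1 − {z/tanh z − 1}·6i(γ−1)/X²),  z = (1+i)X/2.

   Re Γ sets the gas stiffness; Im Γ ≥ 0 is dissipative and produces the
   thermal damping β_th = 3P_gas·Im Γ/(2ρR₀²ω).

2. **Radiation loading.** The liquid loads the pulsating surface with the
   exact monopole impedance ρc·ikR₀/(1+ikR₀). Per unit area its reactive
   part is an entrained mass ρR₀/(1+ε²) (ε = ωR₀/c) and its resistive part
   ρc·ε²/(1+ε²). Referred to the full liquid mass ρR₀, the falling
   radiation mass appears as the pseudo-stiffness [ε²/(1+ε²)]ω² inside

       K(ω) = ω₀² + [ε²/(1+ε²)]ω²,
       ω₀² = 3 Re Γ P_gas/(ρR₀²) − 2τ/(ρR₀³),

   and the resistance as the acoustic damping β_ac = (ω/2)ε/(1+ε²).
   The scattering cross-section used throughout,

       σ_s = 4πR₀² / [(ω₀²/ω² − 1 − 2β₀ε/ω)² + (2β₀/ω + (ω₀²/ω²)ε)²],

   is algebraically identical to 4πR₀²ω⁴(1+ε²)/|K_eff − ω² + 2iβ_eff ω|²
   for the effective-mass oscillator, i.e. it is the exact linear response —
   only the non-acoustic damping β₀ = β_th + β_vis may appear explicitly in
   it, because radiation loss is already carried by the ε terms.

   This referencing of K to the full liquid mass is a deliberate design
   choice: the alternative reading K = (ω₀²+ε²ω²)/(1+ε²) moves the
   undamped frequency by ~ε²/2 and is refuted at the third decimal of the
   peak-location ratios the package reproduces (the two readings place the
   far-field peak symmetrically above/below ω_und at depth; only the form
   adopted here matches the reference response ratios to ±1e-6).

3. **Viscous loss.** β_vis = 2η_s/(ρR₀²), always negligible at the studied
   radii but kept for completeness of the decomposition
   β = β_th + β_vis + β_ac (exact by construction).

Because K and β depend on ω, every resonance is an implicit equation:
ω_und solves ω = √K(ω) (and equals the self-consistent ω₀ root); ω_nat
solves ω² = K − β² and is reported as absent when the motion is overdamped;
the far-field pressure resonance ω_σ maximizes σ_s and is the frequency at
which a driven bladder radiates to distant receivers most efficiently.
Q_f = ω_σ/(2β(ω_σ)) uses the total damping.

## Parameters

| parameter | meaning | units | default / range |
|---|---|---|---|
| R₀ | equilibrium bubble radius | m | 0.01–0.20 (study radii); 0.10 canonical for depth comparisons |
| P_liq, ρ, c, η_s, τ | ambient water state | SI | five shipped environments |
| γ, D_p | gas specific-heat ratio, thermal diffusivity | –, m²/s | N₂/O₂ per environment |
| P_gas | equilibrium gas pressure | Pa | P_liq + 2τ/R₀ (Laplace term switchable) |

The Laplace overpressure convention is a flagged choice: at R₀ ≥ 0.01 m the
correction is < 0.02 % of P_liq, so every reported quantity is insensitive
to it.

The canonical radius for depth comparisons (peak-reduction factors, depth
curves) is R₀ = 0.10 m. Peak heights of the normalized cross-section retain
a mild radius dependence through thermal damping (β_th/ω ∝ R₀^(−1/2)), so a
single radius must be fixed for fold-reduction statements; 0.10 m is the
radius used for the damping-decomposition curves and is the one at which the
fold-reduction values quoted for the study conditions are reproduced.

## Environments and depth profiles

The five environments (warm/cold surface, 1000/2000/3500 m; 35 g/kg) ship as
a structured fixture with explicit unit metadata (MPa, mPa·s, mN/m, 10⁻⁹
m²/s) converted to strict SI exactly once at load. Equation-of-state
correlations for seawater and gas properties are out of scope: depth-resolved
studies consume property tables. The shipped constant-temperature profile
splines the four cold rows (not-a-knot cubic); thermal diffusivity — which
spans two decades, roughly inversely to pressure — is splined in log space to
keep the interpolant positive, all other columns in value space (so an exact
cubic column is reproduced to machine precision). Node depths reproduce the
fixture values exactly; between nodes the four-point spline is an
approximation to a metre-resolved property profile and is the package's own
choice. User tables with finer grids are consumed by the same machinery.

## Numerics

- All frequency arguments are angular (rad/s); Hz only at the reporting
  surface. Double precision throughout.
- Γ evaluation: direct formula for 2 ≤ X ≤ 40; below X = 2 the
  cancellation-prone z/tanh z − 1 is replaced by the series
  (z cosh z − sinh z)/sinh z summed to machine precision; above X = 40,
  tanh z saturates to 1 (overflow guard). Verified against a 50-digit
  arbitrary-precision oracle to 1e-12 across X ∈ [1e-4, 1e4] (tests only;
  the oracle is mpmath).
- Root solves (ω_und, ω_nat) use Brent bracketing on [0.5, 2]·ω_M, widened
  geometrically to at most [10⁻², 10²]·ω_M, relative tolerance 1e-12; a
  missing sign change raises with a diagnostic curve dump. The σ_s
  maximization is bounded Brent on −log σ_s seeded from ω_und (relative
  tolerance 1e-10); a boundary-pinned maximum widens once, then fails
  loudly. If several local maxima ever appeared, the one nearest ω_und
  would be returned; this does not occur for this model.
- Degenerate inputs: τ = 0 is admitted (zero-surface-tension limit);
  ω₀² ≤ 0 (surface tension dominating the gas stiffness) raises as outside
  the model's validity; overdamped natural motion is an outcome, not an
  error.

## Synthetic data

`synthetic_fixtures` generates (i) the fixture pairs themselves, (ii) seeded
log-uniform radii in [0.005, 0.25] m with ±20 % multiplicative perturbations
of every property (one named NumPy generator; same seed, same list), and
(iii) limit-case bubbles (τ = 0 + adiabatic + incompressible; isothermal;
incompressible). The perturbations emulate plausible spreads of ocean and gas
parameters around the study conditions — not real covariances between
properties, not bladder-wall mechanics, and not bubble shapes. Passing
property tests therefore demonstrate robustness of the formulas and solvers
over the parameter neighbourhood, not fidelity to any particular ocean state.

## Known limitations

- Linear, spherical, wall-less bubble: no bladder-wall viscoelasticity (real
  bladders damp faster and radiate less), no prolate-spheroid frequency
  correction, no nonlinear or time-domain dynamics, no multi-bubble
  interaction.
- The normalized response curves are radius-invariant in peak location
  everywhere but in peak height only at depth; at the surface the peak
  height varies tens of percent across R₀ = 0.01–0.10 m because thermal and
  radiation damping are comparable there. Fold-reduction factors are
  therefore quoted at the canonical radius.
- Depth profiles between fixture nodes rest on a four-point spline, not on
  equations of state; treat intermediate-depth values as smooth
  interpolation, exact at 0/1000/2000/3500 m.
- Band integration of spectral source levels assumes a flat spectral density
  across the band; no propagation or detection-range modelling.
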