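# Methods

## Scope and model structure

`flashkin` simulates the chemistry triggered in oxygenated water or a
cell-like medium by ionising radiation delivered with an arbitrary time
microstructure, and converts the resulting peroxyl-radical exposure into a
normal-tissue complication probability. The pipeline has four stages:

1. **Beam** — the prescription (dose, mean dose rate, pulse width, pulse
   count or repetition frequency) becomes a piecewise-constant dose-rate
   function of time, and dose rate becomes molar production through the
   per-species chemical yields (G-values).
2. **Heterogeneous chemical stage** (optional, first microsecond) — track
   chemistry on a periodic 3-D lattice: explicit 7-point diffusion plus a
   stiff per-cell reaction substep, seeded from a species n-tuple.
3. **Homogeneous stage** — from 1 µs to hundreds of seconds the medium is
   treated as well mixed; the production term stays active until the dose
   is delivered and the chemistry then relaxes freely.
4. **Metrics** — AUC-ROO, its normalisation, the logistic NTCP response,
   D50 extraction and the FLASH modifying factor; plus a joint-resampling
   sensitivity harness.

Assumptions: fixed temperature (25 °C rate constants), low-LET radiation,
no spatial structure after 1 µs, no reactive-nitrogen-species chemistry,
and no pH buffering beyond the explicit acid–base reactions.

## Chemical network

The shipped tables contain 39 water-radiolysis reactions and 14
biological-medium extensions (organic pool RH at 1 M, glutathione 6.5 mM,
lipid 1 µM, Fe²⁺ 0.89 µM, catalase 0.08 µM). Bulk water is an explicit
clamped species at 55.3 M so that hydrolysis and proton-transfer reactions
printed with bimolecular units are directly computable; the autoionisation
pair then fixes the neutral-water fixed point [H⁺][OH⁻] = k₂₁[H₂O]/k₂₀
(pH ≈ 7.07), which the test suite verifies by integration to steady state.

Representation choices worth knowing:

- An `A + A` reaction proceeds at rate k·c² and consumes two molecules of
  A per event.
- Untracked ("inert") products of recombination/repair reactions are
  dropped; reactions listing them act as sinks for their reactants.
- Superoxide dismutation (the two `2H⁺ + 2O₂⁻` entries) is implemented as
  second order in O₂⁻ with H⁺ as an unconsumed ambient co-substrate — the
  only reading consistent with the printed M⁻¹s⁻¹ units. Both printed rate
  constants are kept.
- The thiol repair of ROO• (`ROO• + XSH`) has no tabulated XSH
  concentration; XSH is a clamped pool with a configurable effective
  concentration, default 1 M, so the printed constant acts directly as an
  s⁻¹-scale removal rate. This default makes the peroxyl lifetime ~25 s,
  consistent with the integrated-exposure observables the package targets.
- Catalase and Fe²⁺ are clamped (catalyst/regenerated pools); the catalase
  channel consumes one H₂O₂ per reactive event in the tabular encoding
  (reactant1/reactant2 format); the factor-of-two difference to the formal
  stoichiometry only rescales a <0.1 % branch of the H₂O₂ budget.
- The printed rate constants for the HO₂•/O₂⁻ interconversion *via
  hydroxide* imply an acid–base equilibrium opposite to the pKa ≈ 4.8 fixed
  by the direct protonation pair, and make O₂⁻ → HO₂• effectively
  instantaneous. The tables are shipped exactly as printed: the superoxide
  side channel carries ~1 % of the radical flux, so the peroxyl
  observables are unaffected, and the implicit solvers absorb the fast
  mode. Users refining superoxide chemistry should revisit these two
  entries.

## Default chemical yields

The homogeneous stage needs per-species yields at the 1 µs handoff. In the
biological medium the primary radicals never survive to 1 µs as free
species: •OH is scavenged by the 1 M organic pool on ~1 ns, e⁻aq and H• on
~10 ns. The appropriate handoff yields are therefore scavenging-limited
early-time values rather than pure-water escape yields. The shipped
defaults are G(•OH) = 4.3, G(e⁻aq) = G(H⁺) = 4.1, G(H•) = 0.62,
G(H₂) = 0.45, G(H₂O₂) = 0.70, plus the direct-ionisation carbon-radical
yield G(R•) = 0.569 (all molecules/100 eV). The kinetics partition •OH
between RH and glutathione explicitly (≈ 94 % to RH), giving an effective
R• source of ≈ 4.6 molecules/100 eV. For water-only runs the conventional
1 µs escape yields (2.8 / 2.7 / …) are the default. All yields are
configurable per run; the heterogeneous stage can regenerate them from a
lattice simulation via `yields_at_1us`.

## Why dose rate matters in this model

Peroxyl removal is the sum of a pseudo-first-order term (thiol repair,
a ≈ 0.04 s⁻¹) and a second-order self-recombination term (2k₅₁[ROO•]).
Delivery at conventional rates keeps [ROO•] below ~1 µM, where the linear
term dominates and AUC-ROO simply accumulates. FLASH delivery puts the
whole radical load (~5 µM) in place within a fraction of a second, where
self-recombination is comparable to the linear removal, so the integral
drops by tens of percent. Pulse microstructure adds a second-order effect:
concentrating dose into few pulses raises the transient [R•] and its
recombination losses before O₂ capture, shaving a further few percent off
AUC-ROO — visible only at UHDR mean rates.

## Numerical choices

- **Homogeneous integrator**: SciPy BDF with an analytic dense Jacobian,
  rtol 10⁻⁶, atol 10⁻¹² M. Every pulse edge starts a fresh integration
  segment (pulses are microseconds wide inside runs lasting minutes, and
  adaptive steppers would otherwise skip them). On failure the segment is
  retried 100× tighter before raising.
- **Output grid**: geometric spacing per segment, dense enough that the
  trapezoidal AUC changes by < 0.1 % under grid doubling (tested).
  Sub-`atol` negative round-off is clipped to zero in traces.
- **Oxygen**: initialised by Henry's law from the percent oxygenation and
  clamped by default (continuous capillary re-oxygenation picture); a
  depleting-O₂ mode is available (`clamp_o2=False`). The ~3 µM consumed
  per 10 Gy makes the two modes nearly indistinguishable here.
- **Lattice stage**: operator splitting; explicit periodic 7-point
  diffusion with the step capped at the stability bound D·dt/dx² ≤ 1/6
  (auto-reduced and logged), then a linearly-implicit (Rosenbrock–Euler)
  reaction substep batched over cells, with step-doubling error control
  and local extrapolation. The L-stable implicit substep exists because
  the printed water chemistry contains conversion modes up to ~10¹² s⁻¹,
  far beyond what any explicit substep could resolve. Boundary-clamped
  species (O₂) are reset to ambient in the one-cell border shell after
  every macro step; fully clamped species everywhere.
- **D50 extraction**: monotone piecewise-cubic (PCHIP) interpolation of
  the smooth AUC_norm(D) curve, then root-finding of AUC_norm = AUC₅₀
  (exactly the NTCP = 0.5 crossing for any slope γ). This avoids
  oscillatory interpolation through the near-step NTCP curve itself.
- **Ties/degenerate inputs**: molecules exactly on a cell boundary belong
  to the higher cell (half-open intervals); n-tuple records outside the
  lattice are rejected and counted; a sigmoid fit with all observations on
  one side of 0.5, or with all deliveries giving the same AUC, raises a
  non-identifiability error rather than returning a meaningless fit.

## Synthetic track generator

The generator stands in for an external track-structure scorer. Each
history is a straight track entering the top face of the phantom at a
uniform random point, with molecule counts Poisson-distributed around
E/100 eV · G per species, positions uniform along the track and radially
Gaussian (default σ = 5 nm) around its axis, and the direct-ionisation R•
yield included in the same per-track geometry. This preserves what drives
intertrack chemistry — clustered deposition whose local concentration
scales with energy per history and history density — and the tests verify
that denser tracks depress the 1 µs yield. It does not emulate
track-structure physics: no energy-loss straggling, no delta rays, no
angular scattering, no LET dependence, and no sub-picosecond pre-chemical
dynamics. Passing tests therefore validate the reaction–diffusion solver
and the yield bookkeeping, not the physical realism of any particular
radiation quality.

## Sensitivity harness

"Resampled within a ±50 % range" is implemented as an independent
multiplicative factor per parameter, drawn from a normal distribution with
mean 1 truncated at ±2σ with σ = 0.25 (a uniform alternative is provided).
All rate constants and the five biomolecule pool concentrations are
perturbed jointly per draw; draws are deterministic per seed. The summary
reports mean, SD, cv and the cv's Monte-Carlo standard error ≈ cv/√(2n).

Measured behaviour of the shipped chemistry: cv(AUC-ROO) ≈ 12–17 %
(similar at conventional and FLASH rates). This is a direct consequence of
the AUC's analytic elasticities with respect to the two peroxyl-removal
constants (≈ −0.6 for the thiol-repair rate, ≈ −0.4 for self-
recombination): with σ = 25 % per parameter, a sub-10 % output cv is not
attainable under joint resampling of this network. The harness reports
what the stated procedure actually produces rather than a target value.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own desk-scale defaults: homogeneous runs
integrate the full 21-species network to 300 s past delivery; lattice
tests use 4³–16³ cells (the full 50³ lattice is supported and scales
linearly in cell count); the sensitivity harness default is 200 draws,
with 50 used by the acceptance script and 20-draw smokes in the test
suite (the cv standard error scales as cv/√(2n)); dose-response curves
use 5–6 dose points per regime, which PCHIP interpolation resolves to a
D50 stable at the per-mille level.

## Known limitations

- The two superoxide/hydroxide interconversion constants are internally
  inconsistent with the direct-protonation pKa (kept as shipped; see
  above).
- The handoff G-values are configurable estimates, not measurements; all
  concentration-scale outputs inherit their ~±6 % plausible range.
- The lattice stage models a homogeneous oxygenated medium with uniform
  biomolecule pools; organelle structure, membranes and spatially
  localised enzymes are out of scope.
- NTCP parameters are a fitted surrogate for one murine endpoint; no
  claim is made about mechanism or other tissues.
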