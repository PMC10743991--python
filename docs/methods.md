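# Methods

`ionphantom` models the passage of a therapeutic ⁷Li pencil beam
(80–140 MeV/u, 10⁵ histories by default) through six phantom materials —
soft tissue (ST), liquid water (W), PMMA, polystyrene (PS), resin and
epoxy — and computes the tissue-equivalence statistics used to rank the
polymers against the soft-tissue reference.  This note records the model,
its assumptions, the numerical choices, and what the synthetic layers do
and do not demonstrate.

## Materials

A material is a mass density plus an elemental composition; atomic and
mass fractions are interconverted through the atomic masses and always
renormalized to sum to 1 (the packaged compositions are printed rounded
percentages whose sums stray from 100 by up to ~9%).  Each element carries
three lattice energies used by the damage model: the threshold
displacement energy `Ed`, the lattice binding energy `Eb`, and the surface
binding energy `Es` (eV).  Elemental mean excitation energies follow the
ICRU-37/49 convention and ship in `data/elements.csv`; compounds mix them
by Bragg additivity in the logarithm, except where a tabulated compound
value exists (water: I = 75 eV, which additivity underestimates by ~8%).

Two deliberate choices:

* PMMA is packaged at 0.95 g/cm³, the density used by the simulation
  whose result tables this package reproduces; the nominal bulk density
  variant (1.19 g/cm³) ships as `PMMA_bulk`.
* The ST recipe is taken from the material table as printed (H, C, N, O,
  Mg, Cl — including the unusual 1.72 at% chlorine).  Its printed atomic
  number density (8.88 × 10²² cm⁻³) is inconsistent with its own
  composition, which gives 8.29 × 10²²; the composition is authoritative
  and the printed value is carried as a known discrepancy.  This recipe
  has ⟨Z/A⟩ = 0.534 at ρ = 1.0, so its computed ranges fall ~4% above
  water and ~2% below PMMA — the published ST ranges (~15% above water)
  cannot be produced by any Bethe-class stopping model from this
  composition, and the corresponding ordering check is expected to fail.

## Stopping and ranges

Electronic stopping is the Bethe formula with the Barkas effective charge
z\*(β) = z(1 − e^(−125 β z^(−2/3))); relativistic β²γ² terms are included,
shell and density corrections are not (they matter below the ±5% range
tolerance targeted here).  Below a validity floor of 0.1 MeV/u a
velocity-proportional extrapolation (S ∝ √E) matched at the floor is
used.  Nuclear stopping is the ZBL universal reduced-energy fit, summed
over target elements with stoichiometric weights.

CSDA ranges integrate dE/S_total on a log-spaced grid (1024 nodes,
trapezoid in ln E) from the floor to the beam energy, plus the closed-form
residual range of the sub-floor extrapolation (2·E_floor/S_floor ≈ 5 µm —
sub-percent on 40–125 mm ranges).  Range straggling is the Bohr
energy-loss variance (with the relativistic Fano factor) propagated to
range: σ_R² = ∫ ω(E)/S³ dE, typically 0.4–0.5% of range here.

Computed water ranges agree with the published Bragg-peak table to ~1%
(e.g. 109.2 mm vs 108.1 mm at 140 MeV/u), well inside the ±5% the Bethe
approximation justifies; no agreement beyond that is claimed because the
reference code's compound-correction settings are unknown.

## Bragg curves and Monte Carlo transport

The deterministic depth–LET curve inverts the range–energy relation for
the residual energy at each depth (default grid 0.1 mm), evaluates the
total linear stopping there (eV/Å = 0.1 × MeV/mm), and convolves with a
Gaussian of width σ_R to model range straggling.  The peak locator refines
the argmax with a three-point parabola, except at the range-end cusp of an
unblurred curve, where the parabola would straddle the zero cell.

The condensed-history Monte Carlo marches all tracks down a shared energy
grid with 2% relative energy loss per step (~360 steps from 140 MeV/u to
the floor; halving the step changes the mean range by <0.1%).  Per step it
samples a path length (mean ΔE/S, Gaussian with the Bohr variance) and a
Highland multiple-scattering deflection per transverse plane, with
radiation lengths from Tsai's per-element approximation mixed by mass
fraction.  Positions advance in small-angle geometry including the detour
correction (1 − θ²/2).  Beam is along +x, entry face x = 0; a fixed
integer seed makes every endpoint set reproducible.  With straggling and
scattering disabled all endpoints collapse onto the CSDA range — the
consistency identity used in testing.

The projected-range statistics use the population (divisor N) estimator
R_p = Σxᵢ/N, σ = (Σxᵢ²/N − R_p²)^{1/2}; the lateral statistic is
σ_y = (Σ((|yᵢ|+|zᵢ|)/2)²/N)^{1/2}, exactly as defined by the study design
including the absolute values and the /2.  Highland scattering is an
angular model, not a collision-by-collision one, so lateral straggle is
only claimed to ±30% of the reference values; in water at 140 MeV/u the
model gives ~0.83 mm against the published 0.870 mm.

## Displacement damage

The damage model is analytic.  Primary recoils take a Rutherford-like
1/T² spectrum between each element's Ed and the kinematic maximum
transfer; the per-depth nuclear-stopping energy is shared among elements
in proportion to their stoichiometry-weighted ZBL cross-sections.  Each
recoil's non-ionizing energy comes from the Lindhard–Robinson partition
T_d = T/(1 + k·g(ε)) (Robinson fit for g, Thomas–Fermi reduced energy,
compound target averaged by atomic fraction), and the modified
Kinchin–Pease function ν(T_d) — 0 below Ed, 1 on [Ed, 2.5 Ed), 0.8 T_d/2Ed
above — converts damage energy to displacements.  The slowdown is
integrated to 10⁻⁴ MeV/u; the sub-floor budget is deposited in the
track-end bin.

A displacement is classified as a replacement when the collision partners
are the same species and the projectile is left below Ed.  The probability
is estimated analytically: the same-species factor is the atomic fraction,
and the capture factor is the probability that a 1/T²-distributed transfer
bounded below by Eb (softer collisions only excite phonons) lands in the
window [Ed, 2 Ed].  This yields replacement fractions of 2–5% of
displacements, the magnitude characteristic of binary-collision codes.  An
earlier uniform-transfer (hard-sphere) variant gave 15–25% and was
discarded as inconsistent with the 1/T² spectrum used everywhere else.

Energy bookkeeping closes by construction: ionization = beam energy minus
the Lindhard damage budget; stored damage = displacements × Eb; phonons =
the remaining non-ionizing energy.  At therapeutic energies the ionizing
fraction exceeds 99.9%.

**Known limitation.**  The analytic cascade reproduces orderings
(vacancies grow with beam energy; water exceeds soft tissue) and the
per-element recoil shares (water: 65% oxygen vs 64.2% published) but not
absolute cascade counts: the full-slowdown nuclear energy of a 980 MeV
⁷Li ion in water is ~0.5 MeV (consistent with the ~4×10⁻⁴
nuclear/electronic stopping ratio at 100 MeV/u), which after partition
and Kinchin–Pease conversion gives ~2.9×10³ displacements per ion —
roughly 8× the value implied by reading the published collision-event
totals as per-10⁵-ion counts.  Those totals would require a damage energy
(~26 keV/ion) that is also inconsistent with the published recoil-energy
tables (~MeV per track), so the package reports magnitudes from its own
physics and makes no claim of absolute agreement.

The NRT areal normalization N_v = ρ·N_A·Φ_v is implemented with the
standard 1/molar-mass factor (the printed form is dimensionally
incomplete); Φ_v is exposed as a free per-material constant because its
units are not recoverable from the source.

## Comparison statistics

The analysis layer is deliberately convention-explicit, because the
published tables mix conventions (verified by recomputation):

* SD divisor: the Bragg-peak and collision-event tables use the
  population divisor N; the recoil and lateral-straggle tables use the
  sample divisor N−1.
* Percent difference versus the reference material: `of_means` compares
  column means; `mean_of_per_energy` averages the per-energy percent
  differences.  The published Bragg-peak comparisons match the latter
  (PMMA: 7.3%), the collision-event and straggle comparisons the former.
* Sign: positive when the material's values fall below the reference;
  reports carry full precision, display rounds to the printed precision.

The fixture validator recomputes every printed summary cell under these
conventions.  All 60 reproduce exactly at printed precision; the
enumerated known discrepancies (ST number density; two recoil means
printed as 2.835/3.316 vs recomputed 2.8375/3.3200; share rows summing to
99–103; two irreproducible prose percentages) are flagged, never
corrected.

## Synthetic tables

The generator produces material × energy tables
`scale_m · E^1.7 · (1 + ε)`, ε ~ N(0, noise), reproducible by seed.  The
1.7 exponent is the range–energy power law of light ions in the
therapeutic window.  It emulates the structure the analysis assumes
(smooth monotone energy dependence, material-wise scale factors) but not
real-data features such as correlated Monte Carlo noise, heteroscedastic
errors, or table rounding — so planted-truth recovery demonstrates the
analysis layer's correctness, not robustness to those effects.

## Problem sizes and determinism

The default beam uses 10⁵ histories; the test suite exercises the Monte
Carlo at 4×10³–2×10⁴ histories per case, sizes at which the checked
statistics (mean range to 1%, lateral straggle to 30%, monotonicity) are
stable across seeds.  All stochastic outputs carry their seed; the
acceptance script's targets are deterministic and complete in seconds.
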