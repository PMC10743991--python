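# ionphantom

Desk-scale physics of a therapeutic ⁷Li heavy-ion beam in tissue-equivalent
phantom materials, plus the comparison statistics that quantify how closely
each polymer mimics soft tissue.

Heavy-ion therapy delivers most of its dose at the Bragg peak, so phantom
materials used for dosimetry must reproduce the radiological response of the
tissue they stand in for: peak depth, lateral spread, and the secondary
damage interactions (recoils, collision events, phonon release).
`ionphantom` is aimed at medical-physics users who want those quantities for
six packaged materials — soft tissue (ST), liquid water (W), PMMA,
polystyrene (PS), resin and epoxy — without a full Monte Carlo code, and at
analysts who want the tissue-equivalence arithmetic itself (means, standard
deviations, percent differences vs ST, rankings) as a tested library.

## What it computes

* **Stopping & ranges** — Bethe electronic stopping with Barkas effective
  charge z\*(β) = z(1 − e^(−125βz^(−2/3))), ZBL universal nuclear stopping,
  CSDA range R(E) = ∫ dE/S_tot, Bohr range straggling σ_R.
* **Transport** — deterministic depth–LET Bragg curves with peak location,
  and a condensed-history Monte Carlo (2% energy steps, Bohr path-length
  straggling, Highland scattering) yielding track endpoints and the
  straggle statistics R_p = Σxᵢ/N, σ = (Σxᵢ²/N − R_p²)^½ and
  σ_y = (Σ((|yᵢ|+|zᵢ|)/2)²/N)^½.
* **Displacement damage** — Lindhard–Robinson energy partition, modified
  Kinchin–Pease counting ν(T_d) ∈ {0, 1, 0.8T_d/2E_d}, per-element recoil
  shares, vacancy/displacement/replacement bookkeeping, and exact
  energy-conservation closure (ionization + stored damage + phonons = E₀A).
* **Equivalence statistics** — per-material means and SDs over the
  80–140 MeV/u grid (population or sample divisor, explicit), signed percent
  differences vs a reference material, per-20-MeV/u increments, and
  closest-material rankings, applicable to simulator output or to the
  packaged published tables (which ship verbatim, with a validator that
  recomputes every printed summary cell).

## Worked example

```python
from ionphantom import (BeamSpec, Phantom, packaged_material, csda_range,
                        bragg_curve, bragg_peak_position, simulate_tracks,
                        longitudinal_straggle)

water = packaged_material("W")
beam = BeamSpec(140.0, n_particles=10_000, seed=1)   # 7Li, 140 MeV/u

print(round(csda_range(140.0, water), 1))            # 109.2  (mm)
profile = bragg_curve(beam, Phantom(water))
print(round(bragg_peak_position(profile), 1))        # 108.8  (mm)

res = longitudinal_straggle(simulate_tracks(beam, Phantom(water)))
print(round(res.R_p, 1), round(res.sigma_long, 3), round(res.sigma_lat, 3))
# 109.2 0.443 0.831
```

The CSDA range and Bragg-peak depth (109.2 / 108.8 mm) sit within 1% of the
published 108.1 mm for water at 140 MeV/u; the Monte Carlo mean projected
range reproduces the CSDA range, its longitudinal spread matches the Bohr
σ_R (~0.4% of range), and the lateral straggle 0.83 mm is within 5% of the
published 0.870 mm.

The statistics layer on the packaged tables:

```python
from ionphantom import load_fixtures, percent_difference_vs_reference

fx = load_fixtures()
d = percent_difference_vs_reference(fx.table2_bragg, "PMMA", "ST",
                                    mode="mean_of_per_energy")
print(round(d, 1))                                   # 7.3  (% below ST)
```

PMMA's Bragg peak sits 7.3% below soft tissue's — the smallest deviation of
the five candidate materials, which is why PMMA ranks as the closest
soft-tissue surrogate on range.

Command line equivalents:

```
ionphantom simulate --material W --energy 140 --n 100000 --seed 7 --out run/
ionphantom damage --material PMMA --energy 120 --out run/
ionphantom analyze --table bragg --reference ST --mode mean_of_per_energy
ionphantom fixtures validate
```

## Scope and caveats

Primary-ion physics only: nuclear fragmentation, secondary build-up and
beam divergence are out of scope.  Absolute cascade counts from
binary-collision codes are matched in ordering and order of magnitude, not
equality.  `docs/methods.md` records the model assumptions, numerical
choices, and the known inconsistencies in the packaged soft-tissue
reference data.
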