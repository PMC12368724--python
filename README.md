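# secdimer

Analysis of protein homodimer dissociation from size-exclusion
chromatography (SEC), with interface energetics and steady-state enzyme
kinetics. Built around the dimerisation of the GH1 β-glucosidase of
*Spodoptera frugiperda* (Sfβgly, PDB 5CG0), but every stage is generic
to any two-state monomer–dimer system.

**Who it is for:** protein biochemists quantifying weak (μM–mM) dimers
from dilution-series chromatograms, and anyone decomposing mutational
effects on an oligomer interface into free energies.

## The model

A homodimer in a simple equilibrium M + M ⇌ D obeys

```
K_D = [M]² / [D],        C_total = [M] + 2[D]
```

with `[D]` in dimer-molar units. Rearranged, `[M]² = K_D·[D]`: over a
dilution series, a plot of [M]² against [D] is a line through the
origin whose slope is K_D. Peak areas of the monomer and dimer SEC
peaks give the mass fractions (the detector responds per unit mass),
which with the loaded total concentration give [M] and [D] per sample.

Around this core the package provides:

* `simulate` — synthetic SEC dilution series (two Gaussian peaks whose
  areas follow the equilibrium at a chosen true K_D, lognormal area
  noise, linear baseline) and Michaelis–Menten time courses, for
  validating every downstream stage against known ground truth.
* `chromatography` — CSV chromatogram I/O, endpoint-anchored baseline
  subtraction, trapezoidal peak integration over fixed windows.
* `equilibrium` — area→species conversion, the through-origin
  `KdLinearEstimator` and the direct `KdNonlinearEstimator`
  (scikit-learn compatible), and a studentized case-resampling
  bootstrap for the 95% CI.
* `thermo` — ΔΔG⁰_diss = RT·ln(K_D,mut/K_D,wt) between variants,
  absolute ΔG⁰_diss, hydrogen-bond and hydrophobic (54.4 J·mol⁻¹·Å⁻²)
  energy budgets, phosphate-buffer ionic strength.
* `interface` — Shrake–Rupley SASA with a deterministic golden-spiral
  point set, per-residue buried-area bookkeeping between isolated
  chains and the complex, apolar/polar classification, and geometric
  inter-chain hydrogen-bond detection.
* `kinetics` — initial rates from product time courses and a direct
  nonlinear Michaelis–Menten fit (`MichaelisMentenEstimator`) giving
  k_cat, K_m and k_cat/K_m with uncertainties.

## Worked example

Recover a dissociation constant from a simulated dilution series
(truth: K_D = 7 μM, twelve loads of 1–100 μM, 1% area noise):

```python
import numpy as np
import secdimer as sd

cfg = sd.SimulationConfig(true_kd=7.0, c_totals=tuple(np.logspace(0, 2, 12)),
                          noise_cv=0.01, seed=42)
points = []
for chrom in sd.simulate_dilution_series(cfg):
    dimer, monomer = sd.quantify_species_peaks(sd.subtract_baseline(chrom))
    points.append(sd.species_from_areas(monomer.area, dimer.area, chrom.c_total))

fit = sd.fit_kd_linear(points)
(lo, hi), stderr = sd.bootstrap_kd(points, n_boot=1000, seed=0)
print(f"K_D = {fit.kd:.2f} uM  (95% CI {lo:.2f}-{hi:.2f}, R^2 = {fit.r_squared:.5f})")

print(f"ddG(N157S) = {sd.ddg_dissociation(0.028, 0.008):.2f} kJ/mol")
print(f"H-bond budget = {sd.hbond_energy_budget([(2.9, 2), (6.6, 2)]):.1f} kJ/mol")
print(f"hydrophobic(0.32 x 905 A^2) = {sd.hydrophobic_energy(0.32 * 905):.1f} kJ/mol")
```

prints

```
K_D = 7.14 uM  (95% CI 6.63-7.72, R^2 = 0.99995)
ddG(N157S) = 2.90 kJ/mol
H-bond budget = 19.0 kJ/mol
hydrophobic(0.32 x 905 A^2) = 15.8 kJ/mol
```

The fitted slope lands within 2% of the generating K_D and the CI
brackets it. The three energy lines reproduce the interface
bookkeeping for the Sfβgly dimer: the N157S mutation costs 2.9 kJ/mol,
the four interface hydrogen bonds (two symmetry-related pairs at 2.9
and 6.6 kJ/mol) total 19 kJ/mol, and burying 32% of the 905 Å²
interface as apolar surface is worth ≈16 kJ/mol.

The same pipelines are scriptable from the shell via the `secdimer`
console command (`simulate-sec`, `quantify`, `fit-kd`, `ddg`,
`buffer-i`, `interface`, `mm-fit`); see `secdimer --help`.

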