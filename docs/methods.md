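# Methods

## Equilibrium model and estimators

The package treats dimerisation as a two-state equilibrium
M + M ⇌ D with `K_D = [M]²/[D]` and the monomer-equivalent mass
balance `C = [M] + 2[D]`. Solving both gives the closed form

    [M] = 2C / (1 + sqrt(1 + 8C/K_D))

written in conjugate form (algebraically `(−K_D + sqrt(K_D² +
8·K_D·C))/4`) so it stays accurate when `8C ≪ K_D`, where the naive
expression cancels catastrophically.

Two estimators recover K_D from a dilution series:

* **Linear (default).** `[M]² = K_D·[D]` fitted through the origin:
  `K_D = Σ D·M² / Σ D²`. The model has no intercept, so the
  through-origin fit is the default; a free-intercept mode exists
  purely as a lack-of-fit diagnostic. A single point suffices
  algebraically for the origin fit.
* **Nonlinear.** Direct least squares of the predicted dimer mass
  fraction `2D(C, K_D)/C` against observed fractions, optimised on
  log K_D (positivity). On noise-free data both estimators return the
  generating K_D to machine precision; on noisy data they should agree
  within the bootstrap CI, which is used as a cross-method diagnostic.

Samples with dimer mass fraction below 1% or above 99% carry almost no
information about K_D but large leverage; they are flagged with a
warning, never dropped.

### Bootstrap interval

Uncertainty comes from a case-resampling bootstrap of the speciation
points. A log-spaced dilution series concentrates most of the design
leverage `D_i²/ΣD²` in the top one or two samples (≈60% in the default
12-point grid), which shrinks the effective sample size of the variance
estimate far below n; the plain percentile interval then undercovers
materially (≈82–84% observed at nominal 95% in simulation). The
default interval is therefore the **studentized bootstrap-t**: each
resample's slope is pivoted on its HC3 (leverage-corrected) sandwich
standard error, and the t-quantiles are mapped back through the full
sample's HC3 SE. In the same simulations this restores ≈93% coverage.
The percentile interval remains available via `interval="percentile"`.
On noise-free data the interval degenerates to zero width.

## Synthetic data generator

`simulate_dilution_series` emulates a cold-column SEC experiment:

* Two Gaussian peaks, dimer at 25 mL and monomer at 35 mL (σ 0.8 mL),
  on a 20–40 mL grid at 0.02 mL spacing — a tandem analytical
  gel-filtration geometry. All centres/widths are configuration.
* Noise-free areas are `response_factor · C` times the species mass
  fractions; the detector is assumed to respond per unit protein mass,
  identically for monomer and dimer (A280-like). This assumption is
  what licenses mapping area fractions to mass fractions downstream.
* Each area is multiplied by an independent **mean-one lognormal**
  factor of chosen CV — multiplicative noise keeps areas positive and
  mimics injection-to-injection variability. Default CV in validation
  runs is 1%, the scale of a well-behaved autosampler series.
* An optional linear baseline (slope AU/mL, intercept) is added.
* Peaks do not interconvert during elution: the chromatogram is a
  frozen snapshot of the loading equilibrium, the appropriate regime
  for SEC run cold precisely to slow monomer–dimer exchange.

What it does **not** emulate: column dispersion and tailing, on-column
re-equilibration, overlapping peaks, concentration-dependent detector
nonlinearity. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under its own assumptions, not
robustness to those instrument effects.

Kinetics time courses are `product(t) = v0·t` with
`v0 = k_cat·E0·[S]/(K_m+[S])` in nmol/min for the configured assay
(default E0 = 0.09 μM in 100 μL, read at 5/10/15/20 min), plus
Gaussian noise that can be absolute (`noise_sd`, nmol) and/or
proportional to the expected product (`noise_cv`); negative readings
clamp to zero.

## Chromatogram processing

Baseline subtraction fits the line through the means of the first and
last k (default 5) points — valid when the recorded range starts and
ends off-peak, as the default windows guarantee. The operation is
idempotent. Peak areas are trapezoidal integrals over fixed windows
(defaults 22–29 mL dimer, 31–39 mL monomer): with two known species,
fixed windows match how peaks are assigned at the bench and avoid
fragile automatic segmentation. At the default 0.02 mL grid the
trapezoid error on a σ = 0.8 mL Gaussian is ≪0.1%, and window
truncation loses <0.1% of either default peak.

## Thermodynamics

`ΔΔG⁰_diss = RT·ln(K_D,variant/K_D,reference)` with R = 8.314 J/(mol·K)
and default T = 278.15 K (the SEC temperature). The sign convention is
positive = destabilised dimer (variant dissociates more easily).
Absolute `ΔG⁰_diss = −RT·ln(K_D[M])` is against the 1 M standard
state. Variants that never populate the dimer over the accessible
concentration range get a lower bound instead of a number: K_D greater
than the largest determinable K_D in the table, ΔΔG greater than the
corresponding energy.

Hydrophobic stabilisation uses the consensus interface transfer
coefficient 54.4 J/mol per Å² of buried apolar surface; hydrogen-bond
budgets are plain multiplicity-weighted sums of per-mutation ΔΔG
values (a C2 dimer doubles each unique bond).

Phosphate ionic strength: Henderson–Hasselbalch speciation between
H₂PO₄⁻ and HPO₄²⁻ at pKa2 (default 7.20), Na⁺ by electroneutrality,
then `I = ½Σc_i z_i²`. H₃PO₄ and PO₄³⁻ are negligible at pH 5–9 and
ignored; no activity-coefficient correction is applied. For 0.1 M
phosphate at pH 6 this gives I ≈ 0.11 M — values published for such
buffers sometimes differ (e.g. 0.218 M), which cannot be reproduced by
this standard formula under any common pKa choice; the calculator
documents its formula rather than matching any particular published
figure.

## Interface analysis

Shrake–Rupley SASA: per-atom spheres of radius `r_vdW + 1.4 Å` sampled
with a golden-spiral (Fibonacci) point set — deterministic, so results
are reproducible bit for bit. Element radii: C 1.70, N 1.55, O 1.52,
S 1.80 Å (H 1.10 if present; unknown elements require an explicit
fallback radius). 960 points keep the discretisation error under 1%
for protein-sized atoms and reproduce the isolated-sphere closed form
`4π(r+probe)²` exactly (no point of an isolated sphere is occluded);
agreement with an independent SASA implementation on fixtures is at
the 10⁻⁷ level with matched radii and point counts.

Interface residues are found by SASA differencing: each chain's SASA
alone minus in the complex. Because the same point set is used in both
computations and occluders only remove points, per-residue burial is
non-negative by construction. Relative burial is buried/SASA(free
monomer) in percent. Polarity uses the classical apolar set
{G, A, V, L, I, P, M, F, W, Y}; on the published 30-residue Sfβgly
interface inventory this yields 19/30 = 63% apolar.

Hydrogen bonds are detected from heavy atoms only (crystal structures
lack hydrogens): donor capability is inferred from residue templates
(backbone N except proline; sidechain N/O/S known to carry protons)
and acceptors likewise (backbone O; sidechain carboxylates, amide
oxygens, hydroxyls, histidine ring nitrogens). A bond is any
inter-chain donor–acceptor pair within 3.5 Å; no angular criterion is
applied, which trades some specificity for robustness to coordinate
error. Symmetry-related copies report separately, and hydroxyl pairs
capable of donating both ways may appear in both directions.

PDB input is parsed with gemmi (waters dropped, altloc ''/'A' kept);
the analysis itself — SASA, differencing, H-bonds — is implemented
in-package, with biotite's independent SASA used only as a test
oracle. Agreement with published per-residue burial percentages for
real structures is expected only within the spread attributable to
radii conventions and normalisation choices, which published interface
servers do not fully document.

## Kinetics

Initial rates are OLS slopes of product vs time per substrate level
(free intercept: a mixing dead time offsets the intercept, not the
slope). The Michaelis–Menten fit is a direct nonlinear least squares
of `v0 = Vmax·S/(K_m+S)` — no Lineweaver–Burk linearisation, which
distorts the error structure. `k_cat = Vmax / (E0·V)` with the enzyme
amount in nmol; parameter sds come from the fit covariance, and
derived quantities (k_cat/K_m, relative efficiency vs a reference
enzyme) propagate errors to first order assuming independence.

## Problem sizes and tolerances in the validation suite

Recovery checks use 12-sample dilution series (1–100 μM at K_D ≈ 8 μM;
10–1000 μM at K_D = 135 μM) at 1% area noise, matching the span of the
corresponding published experiments; coverage is assessed over 100
replicate experiments with 500 bootstrap resamples each. Kinetics
recovery uses 10 substrate levels (0.1–10 mM) at 2% proportional
noise. Estimator-consistency sweeps cover K_D over 10⁻¹–10⁴ μM;
noise-free identities are asserted at 10⁻⁶–10⁻¹² relative tolerance,
noisy recoveries at 5–10% matching the sd of the respective estimator
under those conditions.

## Known limitations

* Single equilibrium only — no higher oligomers, no kinetic
  (non-equilibrium) SEC.
* Equal per-mass detector response for both species is assumed, not
  estimated.
* The H-bond detector is distance-only and template-based; it does not
  protonate histidines or resolve donor/acceptor ambiguity.
* Energy budgets are strictly additive; no cooperativity between
  interface sites.
* Ionic strength ignores activity coefficients and the temperature
  dependence of pKa2.
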