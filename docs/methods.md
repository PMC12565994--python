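# Methods

## Scope and model

`confspect` post-processes per-conformer quantum-chemistry results for a
small molecule in implicit solvent. It does not run electronic-structure
calculations: geometries, total energies, GIAO shielding tensors and TD
transition lists are inputs, supplied either as a structured YAML ensemble
document (`schema: 1`) or as the packaged reference tables of the
coumarin–cytisine conformer study. The pipeline's stages are independent
and composable; the order below is the order a study runs them.

## Conformer classification (geometry)

Conformers are distinguished by two marker dihedrals between adjacent
carbonyl groups: θ₁ = O1–C19–C45–O4 (cytisine side vs linker) and
θ₂ = O4–C45–C31–O8 (linker vs coumarin side). Dihedrals use the
right-handed IUPAC convention about the central bond and live in
(−180°, 180°]. Note that a torsion angle is *invariant* under traversing
the chain backwards — handedness does not depend on direction — and flips
sign only under mirror reflection; both properties are tested.

Classification: |θ₁| < 90° → group A (conformers 1, 3), otherwise group B
(conformers 2, 4), with |θ₁| = 90° deterministically in B. The family
within a group follows the sign of θ₂ (A: θ₂ > 0 → 1, θ₂ < 0 → 3;
B: θ₂ < 0 → 2, θ₂ > 0 → 4). The study prints marker angles only for
families 1 and 2; the sign rule for 3 and 4 is this package's convention
and classifications carry a `convention_based` flag. θ₂ = 0 exactly leaves
the family "unclassified" (the group is still total).

O···H contact tables report all requested oxygen–hydrogen distances sorted
ascending and can verify a user-supplied strict ordering; ties are reported
as such rather than passed.

## Boltzmann populations (thermo)

Total electronic energies are used directly as state energies — no
zero-point or thermal corrections, mirroring how the reference study
weights its conformers. Populations are
p_r = exp(−(E_r − E_min)/kT)/Z with E_min subtracted for numerical
stability; populations are therefore exactly invariant under any constant
energy shift (tested with binary-exact shifts of ±10⁶ Ha). Constants are
fixed so printed-value comparisons are reproducible:
1 Ha = 627.5094740631 kcal/mol and k = 3.166811563×10⁻⁶ Ha/K; the default
temperature is 298.15 K.

Worth knowing: the printed six-decimal energies reproduce seven of the
study's eight parenthetical relative energies after 2-decimal rounding; the
DMSO conformer-3 cell computes to 0.68 kcal/mol against a printed 0.69.
Likewise the (1+3)/(2+4) population ratio evaluates to ≈0.84 (DMSO) /
≈0.82 (ethanol) from these energies, not the rounder 0.9 quoted alongside
them — presumably higher-precision energies stood behind that figure. The
package computes and tests the honest values.

## Chemical shifts and scaling (nmr)

Isotropic shielding is the mean of the tensor's three diagonal components;
the chemical shift is σ_ref − σ with TMS references σ_ref = 184.32 ppm
(¹³C) and 31.96 ppm (¹H). (The study's text attaches these two numbers to
the nuclei in the reverse order; the assignment here follows the physics —
a TMS carbon shielding of ~184 ppm and proton shielding of ~32 ppm.)

The linear rescaling δ_sc = a·δ + b is an ordinary least-squares fit of
experimental on theoretical shifts (scipy), always per nucleus: the two
references and shift ranges differ by an order of magnitude and a joint
fit would be dominated by ¹³C. The fit reports slope, intercept, RMSE and
R².

## Peak assignment

Within one atom, conformers whose scaled shifts agree to better than the
spectral resolution (defaults: 0.5 ppm for ¹³C, 0.1 ppm for ¹H,
configurable) produce a single predicted peak; per-atom shifts are merged
by single-linkage clustering at that resolution. Experimental peaks and
predicted peaks are then matched by an order-preserving minimum-cost
alignment: both lists sorted by shift, dynamic programming with match cost
|δ_exp − centroid| and a gap penalty equal to the matching tolerance
(defaults: 2.0 ppm ¹³C, 0.3 ppm ¹H).

Why order-preserving rather than nearest-first: in crowded regions an
unrelated atom's shift can fall numerically closer to a peak than the
correct partner (in the reference tables, C15's cluster at 48.0–48.3 ppm
lies 0.08 ppm from the 47.92 ppm peak that belongs to C5's group-B
cluster). A spectroscopist resolves this by walking the spectrum in order,
letting each predicted peak consume the peak at its rank; the monotone
alignment formalizes exactly that and is fully deterministic. A match is
accepted whenever it is cheaper than leaving both sides unmatched (i.e. up
to twice the tolerance); rows whose residual exceeds the tolerance itself
are kept but flagged `within_tolerance=False` rather than silently
dropped. Unassigned peaks and unmatched predictions are reported, not
errors. Printed multiplet ranges match on their midpoint; multiplet
structure is outside the model.

## Group concentration ratio from areas

For every atom with one assigned peak covering only group-A conformers and
another covering only group-B conformers (both with areas), the atom
contributes area_A/area_B (areas summed per side if split further). The
overall estimate is the **median** over atoms — robust to a single
mis-assigned pair. Atoms without a resolved pair are listed as excluded so
the choice of evidence is auditable. Peaks whose conformer set straddles
both groups carry no ratio information and are skipped.

## UV-Vis simulation and processing

Each electronic transition contributes a Gaussian on the **energy** axis
(the broadening width is specified in eV) with σ = FWHM/(2√(2 ln 2)),
FWHM defaulting to 0.25 eV, and peak height equal to its oscillator
strength. Height-proportional intensity (no area normalization, no
E-dependent prefactor) is the conventional way to present TD results when
no molar-absorptivity calibration is intended; the convention is recorded
in the spectrum metadata. The energy-axis profile is sampled on the
wavelength grid (default 200–500 nm, step 2 nm, matching the instrument
settings of the reference study), and the ensemble spectrum is the
population-weighted pointwise sum. Energy/wavelength conversion uses
hc = 1239.84198 eV·nm.

Experimental processing: A = log₁₀(1/T) with T ≤ 0 an error and T > 1
clipped with a warning; normalization divides by the maximum inside a
window (260–350 nm in the study's comparison); background subtraction is
pointwise with negative results floored at zero and the floored-point
count reported. Feature reporting returns strict local maxima plus
shoulders, where a shoulder is defined operationally as a strict local
minimum of |dI/dλ| on a flank whose slope keeps its sign (an
inflection-plateau), with a small relative guard against float noise on
exactly linear stretches. At 0.25 eV FWHM two bands 0.36 eV apart (the
292/319 nm pair) are still resolved into two maxima; a shoulder in this
model appears once the width grows to ≈0.35 eV.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the molecule itself:

* **Ensembles** — per-conformer energies are offsets (kcal/mol) above a
  base energy; defaults are the study's DMSO relative energies
  (0.04, 0, 0.69, 0.43), which place conformers 3+4 at 29% together.
  Geometries come from a minimal abstract O=C–C(=O)–C=O scaffold (built by
  internal-coordinate placement, padded with two hydrogens) that realizes
  the requested marker dihedrals exactly — a synthetic stand-in, not a
  cytisine model, since classification needs only the two dihedrals.
* **Shieldings** — tensors are constructed so the diagonal mean equals
  σ_ref − shift exactly; anisotropic diagonal spread and off-diagonal
  noise never move the mean, so noiseless recovery is exact and Gaussian
  shift noise (sd in ppm) enters only where requested.
* **Peak lists** — one peak per resolved atom-cluster, area =
  Σ populations × proton count × a mean-one log-normal factor
  (multiplicative noise keeps areas positive; coefficient of variation is
  the knob).
* **Spectra** — a transition template (default: the most stable
  conformer's five printed transitions) broadened and Boltzmann-weighted,
  with optional per-conformer energy jitter, additive baseline and
  Gaussian noise.

All generators are pure functions of (config, seed); independent
operations draw from independent seeded streams.

What passing synthetic tests does and does not show: recovery of the
scaling parameters (a within ±0.02, b within ±0.5 ppm at σ = 0.1 ppm,
n = 50) and of the group ratio (within 5% at 2% area noise) demonstrates
the estimators are consistent under the assumed noise model — Gaussian
shift errors, multiplicative area errors, well-separated clusters. Real
spectra add multiplet structure, overlapping peaks, baseline drift and
solvent signals that the generator deliberately omits; the solvent peak in
the packaged tables (39.5 ppm) is handled by the assignment's gap
mechanism, not by a solvent model.

## Numerical choices and degenerate inputs

* Exact energy ties need no special casing in the Boltzmann weights.
* Collinear atoms make a dihedral undefined → explicit geometry error.
* Assignment ties are broken deterministically (match preferred over
  skipping the peak, over skipping the prediction; stable sorts by label).
* The transition energy/wavelength consistency check allows 0.015 nm —
  the printed table's own rounding reaches 0.010 nm.
* Spectra must be strictly monotonic in their axis; descending files are
  resorted with a logged warning, never silently.

## Problem sizes

Tests and the acceptance script run on the printed four-conformer tables
(42 ¹³C rows, 28 ¹H rows, 21 transitions), 50-point synthetic scaling
fits, 5-atom synthetic peak lists, and 10³–10⁴-point spectral grids; the
full suite completes in a few seconds on one CPU.

## Known limitations

* No vibrational/thermal free-energy corrections or conformational
  entropy beyond Boltzmann weighting; no solvation-model computation.
* No spin–spin coupling, multiplet simulation or 2D NMR; assignment works
  on peak positions and areas only.
* No vibronic structure or solvent-shift modelling in UV-Vis; no fitting
  of experimental band shapes to conformer mixtures.
* The ensemble schema does not parse raw quantum-chemistry log files; an
  adapter could be added behind `read_ensemble` without touching the
  analysis layers.
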