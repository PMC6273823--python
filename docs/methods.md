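# Methods

## Scope and model

`cdftkit` implements the conceptual-DFT post-processing layer for studies
of Michael-acceptor enones (piperidin-4-one curcuminoids and relatives):
given electronic-structure records for neutral molecules and their radical
anions, it computes global and condensed local reactivity indices,
electron attachment/detachment energetics, substituent (Hammett)
correlations, SOMO delocalization diagnostics and torsional grid scans.
The electronic-structure calculations themselves (DFT optimizations,
frequencies, semi-empirical surfaces) are out of scope by design: records
are consumed, and the torsion scanner takes an energy callback so an
external engine can be plugged in.

## Units, rounding, validation

Energies are stored in Hartree and converted to eV only at reporting
boundaries, with a single CODATA factor (27.211386245988 eV/E_h). Report
tables round half-away-from-zero to 2 decimals (global indices) or 3
decimals (attachment and condensed indices). Record validation is total:
orbital ordering, occupation ranges (closed-shell single-channel dialect
up to 2 per orbital, per-spin dialect up to 1), electron-count consistency
with the geometry (1e−6), anion charge = −1, non-negative ZPVE, overlap
symmetry/unit diagonal (1e−8) and MO normalization cᵀSc = 1 (1e−6); every
violation carries a machine-readable name.

## Global indices

μ = (ε_H + ε_L)/2, η = (ε_L − ε_H)/2 (the convention carrying the ½
factor, fixed by the tabulated values η = gap/2), ω = μ²/(2η) computed
from *unrounded* μ and η. The HOMO is the highest orbital with occupation
> 0.5 per spin orbital; for open-shell records the α channel defines the
frontier. Rankings by ω use a 0.005 eV tie threshold, matching 2-decimal
reporting. The source tabulation mixes rounding conventions (two ω cells
differ by 0.02–0.03 from any single convention, and one printed gap cell
contradicts its own row — see `src/cdftkit/data/fixture_notes.txt`);
identity tests therefore use ±0.01 eV (gap, μ, η) and ±0.03 eV (ω) bands
rather than chasing the source's rounding.

## Attachment energetics

AEA/VEA/VDE follow the neutral-minus-anion sign convention (positive AEA:
the relaxed anion is bound). E = E_elec + ZPVE at stationary points only.
Vertical points are not stationary — no frequencies exist there — so
vertical differences use electronic energies alone; this equals assigning
each vertical species its stationary parent's ZPVE, which cancels in the
difference. This is the one necessary deviation from a blanket
"E = E_elec + ZPVE" prescription and is deliberate. Composite-level
energies add a small-basis ZPVE to a large-basis single-point energy. The
bracket VEA ≤ AEA ≤ VDE is checked with 1e−9 eV slack (pure float noise,
three orders below the 1e−3 eV reporting precision); it is a *check*
because published tables can violate it — the packaged table does, in
exactly one documented cell.

## Population analysis and condensed indices

Mulliken partitioning is the default condensation scheme (the scheme is
rarely stated in this literature; Mulliken is the default of the common
quantum-chemistry codes), with externally supplied charges accepted as an
alternative. Gross atomic population: Σ_{μ∈A}(P·S)_{μμ}; spin populations
from (P_α − P_β)·S. Condensed f⁺_k = q_k(N) − q_k(N+1), the standard
finite-difference form for nucleophilic attack, summing to 1; P⁺ is the
anion's atomic spin density, renormalized to unit sum by default
(tolerance 1e−3 on the raw sum absorbs population round-off). P⁺ is taken
at the anion-optimized geometry because the anions are optimized species
in this workflow; a vertical choice is possible by feeding the vertical
record instead. Site comparison uses a 5e−4 tie threshold (3-decimal
printing); C7 preference maps to 1,4-(conjugate) addition, C9 to
1,2-addition.

SOMO classification: fragment weights w_F = Σ_{μ∈F} c_μ(Sc)_μ; small
negative Mulliken weights are reported raw but clipped for
classification. "Dipole-bound" requires max weight ≥ 0.85 with the
second-largest < 0.10 — invented but configurable thresholds, since the
literature offers only qualitative orbital pictures; the delocalization
ratio (participation ratio over fragments, normalized to (0,1]) is
reported alongside so users can apply their own cutoff. Fragment
boundaries are user configuration; the packaged toy geometry labels the
enone atoms C7/C8/C9/O9.

## Hammett stage

Ordinary (unadjusted) R² from closed-form OLS, exposed statsmodels-style
as `HammettModel(...).fit() → HammettResults` with coefficient standard
errors and `summary()`. The default σ_p table (H 0.00, Cl 0.23, Br 0.23,
NMe₂ −0.83, CN 0.66, CF₃ 0.54) is the standard Hansch–Leo–Taft
compilation and is user-overridable; because σ compilations differ at the
0.01–0.05 level, agreement with published R² values is asserted at ±0.03.
With these defaults the packaged basis-1 AEA series for compounds 1–6
gives R² = 0.902 against a published 0.89.

## Torsion scans

Rigid-rotor dihedral driving: connectivity from covalent radii × 1.2, the
component distal to the central bond rotated by Rodrigues' formula
(ring bonds are rejected — no partition exists). Grids default to 15°
(24 × 24 for two dihedrals, mirroring typical semi-empirical
conformational analyses); argmin ties break to the lexicographically
smallest (θ₁, θ₂). Energies come from the callback; packaged analytic
cosine surfaces with known minima validate the scan logic. No published
numeric anchor exists for this stage (the source reports neither grid nor
located minima), so its guarantees are property-based: isometry of the
rotation, argmin correctness, monotone non-increase of the minimum under
grid refinement.

## Synthetic data

Generators invert each analysis stage exactly rather than simulating
electronic structure: a requested frontier pair, attachment triple
(requiring the physical ordering), condensed-index vector or Hammett line
is embedded in valid records with seeded random absolute energies, filler
orbitals and padding populations. This gives bit-reproducible ground
truth at zero compute cost. What it does *not* emulate: basis-set
effects, correlation between descriptors, realistic DFT noise, or
geometry relaxation — so a green round-trip test establishes the
bookkeeping and conservation laws, not the accuracy of any
electronic-structure method. The packaged tables ship exactly as printed
(two documented inconsistent cells included, sha256-pinned); the
Hammett noise model is i.i.d. Gaussian on the descriptor with
user-chosen σ (default 0 for exact inversion; 0.05 eV in the Monte-Carlo
recovery tests, a typical scatter for substituent series of this size).

## Known limitations

- Only Mulliken condensation is implemented in-package; Hirshfeld/NPA
  enter via pre-condensed external charges.
- Anion records are assumed singly charged doublets of neutral
  closed-shell parents.
- The dipole-bound heuristic inspects fragment weights only; it cannot
  see diffuse-orbital character that a basis-space partition misses.
- The rigid-rotor driver does not relax the remaining degrees of freedom;
  scans are unrelaxed by construction.
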