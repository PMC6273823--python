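# cdftkit

Conceptual-DFT reactivity analysis for Michael-acceptor enones — in
particular the two series of *N*-methyl and *N*-benzyl piperidin-4-one
curcuminoids (twelve compounds with H, 4-Cl, 4-Br, 4-NMe₂, 4-CN and 4-CF₃
aryl substituents).

The package is the *post-processing* layer of such a study: it consumes
electronic-structure records (energies, ZPVE, orbital energies and
occupations, optionally density/overlap matrices or pre-condensed atomic
populations) produced by any quantum-chemistry program, and computes every
derived reactivity quantity. It does **not** run DFT or semi-empirical
calculations itself; a pluggable energy callback lets the torsion scanner
drive an external engine.

## What it computes

For frontier orbital energies ε_H (HOMO) and ε_L (LUMO), the global
indices are

- chemical potential  μ = (ε_H + ε_L)/2
- hardness       η = (ε_L − ε_H)/2
- electrophilicity    ω = μ²/(2η)

For a species with optimized neutral (n) and radical-anion (a) geometries,
with E = E_elec + ZPVE at stationary points,

- AEA = E(n, opt) − E(a, opt)   (adiabatic electron affinity)
- VEA = E_elec(n, opt) − E_elec(a at n's geometry)   (vertical)
- VDE = E_elec(n at a's geometry) − E_elec(a, opt)   (vertical detachment)

with the physical bracket VEA ≤ AEA ≤ VDE checked, not assumed, and a
composite-basis mode (large-basis single point + small-basis ZPVE).

Local electrophilicity at the conjugate-addition site C7 (β-carbon) and
the direct-addition site C9 (carbonyl carbon) of the C7=C8−C9=O9 enone
fragment is condensed per atom as

- Fukui function  f⁺_k = q_k(N) − q_k(N+1)  (charges at the neutral geometry)
- Parr function  P⁺_k = atomic spin density of the doublet radical anion

from Mulliken populations (`population` module) or externally supplied
charges. Hammett regressions of any descriptor against σ_p, radical-anion
SOMO classification (valence- vs dipole-bound from fragment-resolved MO
composition), and two-dihedral torsion grid scans round out the pipeline.

## Worked example

```python
from cdftkit import global_reactivity, rank_by_omega
from cdftkit.synthetic import load_fixture

gi = global_reactivity(-6.01, -2.09)   # compound 1 frontier energies, eV
print(f"mu = {gi.mu:.2f} eV, eta = {gi.eta:.2f} eV, omega = {gi.omega:.2f} eV")
```

prints

```
mu = -4.05 eV, eta = 1.96 eV, omega = 4.18 eV
```

i.e. the unsubstituted *N*-methyl compound is a moderate electrophile;
repeating this over the packaged table of all twelve compounds and ranking
by ω reproduces the substituent trend CN > CF₃ > Cl = Br > H > NMe₂ in
both series. The full pipeline on the packaged reference tables:

```bash
cdftkit demo --output demo_out --seed 0
```

which writes the three report tables, Hammett fits (e.g. basis-1 AEA vs
σ_p for compounds 1–6: R² = 0.902), an anion-classification summary and a
run manifest, and prints the ω ranking plus the one attachment-energy row
whose printed values violate VEA ≤ AEA ≤ VDE (a documented transcription
error; see `src/cdftkit/data/fixture_notes.txt`).

Records are JSON files (schema in `cdftkit.io`); a directory of them is
analysed with `cdftkit run --input records/ --output out/`, and individual
stages with `cdftkit validate|global|ea|local|hammett|scan`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds, for each tabulated target compound, a synthetic closed-shell
record whose frontier orbitals equal the tabulated HOMO/LUMO energies,
runs it through frontier extraction and the global-index computation, and
writes the resulting μ, η or ω values (2-decimal reporting precision) as
JSON.
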