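# tpistab

Oligomeric-state and thermal-stability analysis for TIM-barrel proteins —
written around the question of whether a thermoacidophilic archaeal
triosephosphate isomerase (TPI) is a dimer or, like its thermostable
relatives, a tetramer.

The package is for protein biophysicists who have (or simulate)
equilibrium analytical-ultracentrifugation scans, single-wavelength CD
melt traces, and apo/ligand-bound structure pairs, and want the standard
analysis chain as tested, scriptable code:

* **Sequence-derived parameters** — molecular weight, ε₂₈₀ (Pace or
  Gill–von Hippel coefficients), and temperature-corrected Cohn–Edsall
  partial specific volume; buffer density from component molarities.
* **Sedimentation equilibrium** — forward models
  `C(r) = C_b·exp[A_p·nM_p·(r²−r_b²)] + ε` (homogeneous n-mer) and the
  reversible monomer/n-mer extension with ln k on the absorbance scale,
  where `A_p = (1−v̄ρ)ω²/2RT`; joint least-squares fits over speeds and
  loadings; model selection by weighted SSQ/RMS with degeneracy flags and
  a Wald–Wolfowitz runs test on the residual signs.
* **Thermal melts** — two-state van't Hoff fit with linear baselines,
  reporting the apparent half-denaturation temperature T_d and ΔH_vH.
* **Structure comparison** — Kabsch superposition, all-chain-pair Cα
  RMSD, per-residue displacement between conformers, protein–ligand
  contact tables, proline content and segment hydrophobicity (Eisenberg
  consensus scale).
* **Synthetic data generators** that emulate the underlying study design
  (2 rotor speeds × 3 loading concentrations, monomer mass 24,671 Da,
  ε₂₈₀ 11,920 M⁻¹cm⁻¹, v̄ 0.7417 cm³/g, ρ 1.00704 g/cm³ at 20 °C), so the
  whole pipeline is testable without downloads.  The structure pair and
  sequence shipped for testing are synthetic stand-ins; see
  `docs/methods.md`.

## Worked example

Simulate an equilibrium run from a homogeneous dimer truth and ask which
model the data support:

```sh
$ tpistab fit-auc --seed 1 --outdir out
verdict: homogeneous 2x model
        2x  RMS = 4.891e-03
        1x  RMS = 1.039e-01
        4x  RMS = 1.203e-01
```

The dimer (2x) model beats monomer and tetramer by ~20× in RMS; the
per-model fit table and residuals land in `out/` as TSV.  The same run in
Python:

```python
from tpistab import (HomogeneousModel, ModelSpec, StudyDesign,
                     fit_model, generate_auc_dataset, select_model)

design = StudyDesign()                       # the study conditions
truth = HomogeneousModel(monomer_mass=design.monomer_mass, n=2)
scans = generate_auc_dataset(truth, design, seed=1)
fits = [fit_model(scans, ModelSpec("homogeneous", n, design.monomer_mass),
                  design.buoyancy()) for n in (1, 2, 4)]
print(select_model(fits).selected.label)     # -> 2x
```

Sequence/solution parameters and the other stages:

```sh
$ tpistab params
molecular_weight_Da: 24671
eps280_M_cm: 11920
vbar_cm3_g: 0.74151
buffer_density_g_cm3: 1.007
proline_pct: 4.2
helix5_hydrophobicity: -0.357

$ tpistab fit-melt --seed 2
Td = 74.6 C, dHvH = 450 kJ/mol, fit RMS = 3.06e-14

$ tpistab compare-structures
best chain pairing A/D: Ca RMSD 0.69 A over 216 residues
residue 143 moved 8.2 A
residue 175 moved 3.7 A
```

`params` reports the monomer mass (24,671 Da), the reduced-Cys extinction
coefficient (8 Tyr × 1490), the partial specific volume at 20 °C, the
density of the 20 mM Tris-HCl / 200 mM NaCl buffer, the proline content
of the 216-residue chain, and the mean Eisenberg hydrophobicity of the
charged helix-5 segment.  `compare-structures` superposes the apo and
ligand-bound forms (here the built-in synthetic stand-in pair), reports
every chain pairing, and quantifies how far the two active-site loop
markers close over the ligand.

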