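# Methods

`tpistab` implements the biophysical workflow used to establish the
oligomeric state and thermal stability of a thermoacidophilic archaeal
triosephosphate isomerase (TPI): sequence-derived solution parameters,
equilibrium-sedimentation model fitting and selection, two-state melt
fitting, and quantitative apo/ligand-bound structure comparison.  This note
records the models, the defaults and the design choices; every number cited
here is computed by the test suite or the CLI, not transcribed from
elsewhere.

## Sequence-derived parameters

Molecular weight is the sum of average-isotopic residue masses plus one
water (18.0153 Da).  The 280-nm extinction coefficient uses the Pace (1995)
coefficients, eps = 5500 nTrp + 1490 nTyr + 125 ncystine, with the fully
reduced convention (0 cystines) as default and Gill & von Hippel available
as an alternative.  The partial specific volume is the mass-weighted
Cohn–Edsall average of per-residue values at 25 °C, shifted by the standard
linear rule 4.25×10⁻⁴ cm³ g⁻¹ K⁻¹.  An expression construct's tag (e.g. a
C-terminal LEHHHHHH) is held as a separate composition so that
whole-construct mass and ORF-level metrics coexist.

Buffer density is water density (Kell 1975 polynomial) plus a linear
increment per solute, c·(M − ρ_w·φ_v)/1000, with dilute-limit apparent
molal volumes embedded for NaCl (16.62 cm³/mol), Tris-HCl (134.9), HEPES,
imidazole and glycerol.  Tris-HCl enters at its formal molarity without pH
speciation, the convention of the sedimentation-interpretation programs
this calculation mirrors.  For 20 mM Tris-HCl + 200 mM NaCl at 20 °C the
result is 1.00703 g/cm³.

## Sedimentation equilibrium

With the reduced buoyancy factor A_p = (1 − v̄ρ)ω²/(2RT) (CGS units,
R = 8.31446×10⁷ erg mol⁻¹ K⁻¹, radii in cm), the homogeneous n-mer profile
is C(r) = C_b·exp[A_p·nM_p·(r² − r_b²)] + ε and the reversible
monomer/n-mer profile adds C_bⁿ·exp[ln k + n·A_p·M_p·(r² − r_b²)], with k
the association constant on the absorbance concentration scale.  The
reference radius is the cell bottom; the meniscus only bounds valid data.
Exponentials are clipped at ±700 to guard overflow.

Fitting uses damped least squares (SciPy's trust-region-reflective
variant, chosen over the classical unconstrained Levenberg–Marquardt so
C_b ≥ 0 can be enforced).  Joint fits over multiple scans share the model
parameters (free monomer mass, ln k) and give each scan its own (C_b, ε);
the fixed-mass homogeneous candidates therefore fit two parameters per
scan.  Starts are data-derived: ε from the meniscus absorbance, C_b from
bottom-minus-meniscus.  Weighting is uniform by default (no scheme is
implied by the printed statistics this mirrors); per-point weights can be
passed.  The reported RMS is sqrt(SSQ/(N − p)) with a raw-denominator
option, since the source statistic's denominator is not defined anywhere.

Model selection ranks candidates by RMS with three plausibility flags:

* **collapsed association, low side** — a reversible fit with
  ln k < −20: the n-mer term has switched off and the "equilibrium" is a
  disguised monomer fit;
* **collapsed association, high side** — the monomer term carries < 5% of
  the bottom signal: the fit degenerated onto a pure n-mer.  On data that
  truly contain one homogeneous species the reversible model has a flat
  ridge along which one term vanishes; which edge the optimizer reaches
  depends on the data, and both edges mean the same thing — no detectable
  equilibrium;
* **non-convergence**.

RMS differences within a 1% relative parsimony margin count as ties and go
to the model with fewer parameters, so a degenerate extra parameter that
soaks a fraction of a percent of noise cannot displace the simpler model.
Residual-sign randomness is reported per candidate via a Wald–Wolfowitz
runs test using the exact conditional run-count distribution given the
sign counts (two-sided p = twice the smaller tail, capped at 1).  When all
residuals share one sign the conditional law is degenerate; the p-value
then comes from enumerating the 2ⁿ equiprobable sign assignments
(p = 2^(1−n)).

## Thermal melts

A single-wavelength melt is fitted as a two-state van't Hoff transition
with linear folded/unfolded baselines; f(T) = 1/(1 + exp[−(ΔH_vH/R)(1/T −
1/T_d)]) in Kelvin, ΔC_p fixed at zero (apparent T_d, matching the
convention of the anchor values).  Baselines are initialized from the
outer sixths of the trace and the midpoint from the 0.5-crossing of the
baseline-normalized signal; if no crossing exists, or the two baseline
fits are indistinguishable, the fit refuses with a "transition not
bracketed" error rather than extrapolating.

## Structure comparison

Superposition is the closed-form Kabsch solution (SVD with determinant
correction); collinear sets are rejected.  Cα RMSD is computed after
superposition over a same-residue-number, same-residue-type mapping;
residues missing a Cα are dropped with a warning and the count used is
reported.  Because which of the four chains produced the published global
RMSD is not recorded, all chain pairings are computed and reported.
Per-residue displacement is the distance between an atom and its
superposed counterpart, Cα by default.  Hydrogen bonds are operationalized
purely as heavy-atom distance cutoffs (default 3.5 Å, no angle term),
since the claims being reproduced are distance-level.  Altlocs resolve to
the highest occupancy (ties toward 'A'); waters are excluded from
superpositions and contacts unless selected.  Parsing is delegated to
gemmi (PDB and mmCIF).

## Synthetic data: what it emulates and what it does not

No raw scans, melt traces or (in an offline build) deposited coordinates
are available, so the generators reproduce the *study design* and the
package is validated by parameter recovery rather than by refitting the
original data.

* **AUC**: 2 speeds (20,000/26,000 rpm) × 3 loadings (12.6/16.8/21.0 µM),
  monomer mass 24,671 Da, ε₂₈₀ 11,920 M⁻¹cm⁻¹, v̄ 0.7417 cm³/g, ρ 1.00704
  g/cm³, 20 °C, Gaussian absorbance noise sd 0.005 AU.  Loading molarity
  is converted to absorbance with a 1.2 cm six-sector optical path and the
  bottom concentration follows from exact sector-shaped mass conservation.
  The radial window (6.9–7.2 cm, 130 points) is a short-column convention,
  not a reported value.  Real scans additionally contain baseline drift,
  window artifacts and concentration-dependent nonideality; passing the
  recovery tests shows the estimator works under the stated noise model,
  not that those artifacts are handled.
* **Melts**: two-state truth anchored at apparent T_d 74.6 °C (and
  107.1 °C for the tetrameric comparison protein), ΔH_vH 450 kJ/mol and
  mdeg-scale baselines chosen as typical for a ~50 kDa helical dimer at
  222 nm; noise is white Gaussian, while real CD melts show slow baseline
  wander and scan-rate effects.
* **Structures**: the deposited apo/ligand-bound pair is represented by a
  *synthetic stand-in*: a four-chain idealized Cα scaffold of a
  216-residue surrogate sequence constructed once to satisfy the published
  composition anchors exactly (no Trp, 8 Tyr, 9 Pro, construct mass
  24,671 Da, v̄(20 °C) ≈ 0.7417) with the catalytic/marker residues at
  their author numbers.  The bound form differs by a displacement field
  with designed loop-marker moves of 8.3 Å (residue 143) and 3.8 Å
  (residue 175) toward the ligand site plus an isotropic background scaled
  so the per-chain Cα RMSD is exactly 0.69 Å, and carries an idealized
  glycerol-3-phosphate-like ligand whose contacts to the catalytic
  glutamate (≤ 3 Å to O1/O2) and to four backbone nitrogens (≤ 3.5 Å to
  the phosphate oxygens) hold by construction.  It validates the geometry
  code end-to-end; it says nothing about the real crystal structures.

Every generator is a pure function of (truth, design, seed).

## Problem sizes and numerical choices

The Monte-Carlo acceptance checks use 200 replicate AUC datasets (6 scans
× 130 points each) for model selection and free-mass recovery, and 100
noisy melt replicates (2% of the transition amplitude) for T_d bias; both
run in seconds because the fixed-mass fits are two parameters per scan.
Optimizer tolerances are SciPy defaults; the free monomer mass is scaled
by its magnitude to keep the trust region well conditioned.  Degenerate
inputs are defined rather than accidental: an empty composition has the
mass of water (flagged), vbar of an empty composition is an error, a
zero-speed rotor gives A_p = 0, and a single-sign residual vector reports
the enumeration p-value.

## Known limitations

No pKa/charge or hydrodynamic-shape calculations; no viscosity or
refractive index; no CD spectral deconvolution; no heat-capacity
(calorimetric) fitting — the ΔC_p = 0 convention means fitted ΔH_vH values
on real data are apparent; contacts are distance-only; the
synthetic-structure stand-in is not a substitute for the deposited
coordinates when real structural numbers are needed.
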