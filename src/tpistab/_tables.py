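"""Embedded physical-constant tables for sequence- and solution-derived parameters.

Sources (standard compilations, embedded so the package runs without
downloads):

* Average-isotopic amino acid *residue* masses (Da), i.e. the free amino
  acid minus one water; IUPAC 1997 atomic weights.
* Cohn-Edsall per-residue partial specific volumes at 25 degC (cm^3/g), the
  set conventionally used for composition-based vbar estimates in
  sedimentation analysis (Laue et al. 1992 compilation).
* Pace (1995) and Gill & von Hippel (1989) molar extinction coefficients at
  280 nm (M^-1 cm^-1).
* Eisenberg (1984) normalized consensus hydrophobicity scale.
* Buffer-component molar masses and dilute-limit apparent molal volumes
  (cm^3/mol) for linear density increments (Laue et al. 1992 style).
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic-averaged residue masses in Da (residue = amino acid - H2O).
RESIDUE_MASS_DA: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS_DA = 18.0153

#: Cohn-Edsall partial specific volumes at 25 degC, cm^3/g.
RESIDUE_VBAR_25C: dict[str, float] = {
    "A": 0.74, "R": 0.70, "N": 0.62, "D": 0.60, "C": 0.63, "Q": 0.67,
    "E": 0.66, "G": 0.64, "H": 0.67, "I": 0.90, "L": 0.90, "K": 0.82,
    "M": 0.75, "F": 0.77, "P": 0.76, "S": 0.63, "T": 0.70, "W": 0.74,
    "Y": 0.71, "V": 0.86,
}

#: Temperature correction applied to the 25 degC vbar (cm^3 g^-1 K^-1).
VBAR_TEMP_SLOPE = 4.25e-4

#: 280-nm molar extinction coefficients, M^-1 cm^-1.
EXTINCTION_280: dict[str, dict[str, float]] = {
    # Pace et al. 1995
    "pace": {"W": 5500.0, "Y": 1490.0, "cystine": 125.0},
    # Gill & von Hippel 1989
    "gill-von-hippel": {"W": 5690.0, "Y": 1280.0, "cystine": 120.0},
}

#: Eisenberg et al. 1984 normalized consensus hydrophobicity scale.
EISENBERG_CONSENSUS: dict[str, float] = {
    "I": 0.73, "F": 0.61, "V": 0.54, "L": 0.53, "W": 0.37, "M": 0.26,
    "A": 0.25, "G": 0.16, "C": 0.04, "Y": 0.02, "P": -0.07, "T": -0.18,
    "S": -0.26, "H": -0.40, "E": -0.62, "N": -0.64, "Q": -0.69, "D": -0.72,
    "K": -1.10, "R": -1.76,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "eisenberg-consensus": EISENBERG_CONSENSUS,
}

#: Buffer components: molar mass (g/mol) and dilute-limit apparent molal
#: volume (cm^3/mol).  The linear density increment of a component at
#: temperature T is (M - rho_water(T) * phi_v) / 1000 per mol/L.
SOLUTE_COMPONENTS: dict[str, tuple[float, float]] = {
    "NaCl": (58.443, 16.62),
    "Tris-HCl": (157.596, 134.90),
    "HEPES": (238.301, 160.1),
    "imidazole": (68.077, 60.8),
    "glycerol": (92.094, 70.95),
}

#: Validity range of the water-density polynomial and solute increments (K).
SOLUTION_TEMP_RANGE_K = (273.15, 373.15)

#: Gas constant in CGS units, erg mol^-1 K^-1 (for the sedimentation
#: exponent with radii in cm and molar masses in g/mol).
R_GAS_CGS = 8.31446e7

#: Gas constant in kJ mol^-1 K^-1 (van't Hoff fitting).
R_GAS_KJ = 8.31446e-3
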