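"""Synthetic data generators emulating the study design.

No raw centrifuge scans, melt traces or (in an offline build) deposited
coordinates ship with this package, so every pipeline stage is exercised on
synthetic inputs generated here.  Each generator is a pure function of
(truth parameters, design, seed) and produces outputs that satisfy the
consuming types' invariants by construction.

The defaults mirror the equilibrium-sedimentation study design this package
was written around: six-sector cells, rotor speeds 20,000 and 26,000 rpm,
loading concentrations 12.6/16.8/21.0 uM, monomer mass 24,671 Da,
eps280 = 11,920 M^-1 cm^-1, vbar = 0.7417 cm^3/g, buffer density
1.00704 g/cm^3 at 20 degC, and Gaussian absorbance noise.  The melt
generator is anchored at apparent Td values of 74.6 degC (the dimeric
archaeal TPI) and 107.1 degC (the tetrameric comparison protein).

The module also provides a *synthetic stand-in* for the apo/ligand-bound
crystal-structure pair: idealized coordinates constructed so that the
published comparison geometry (global C-alpha RMSD 0.69 A over 216 residues,
loop-6/loop-7 marker displacements of 8.3 and 3.8 A toward the ligand, and
sub-3-A catalytic-carboxylate contacts to the ligand O1/O2) holds by design.
It reproduces the measurement geometry, not real stereochemistry, and is
labelled synthetic wherever it appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .composition import ResidueCounts
from .melt import MeltCurve, TwoStateParams, predict_signal
from .sedeq import (
    BuoyancyContext,
    HomogeneousModel,
    RadialScan,
    ReversibleModel,
    RotorCondition,
    predict_homogeneous,
    predict_reversible,
    reduced_buoyancy,
)
from .structure import (
    Atom,
    ONE_TO_THREE,
    StructureModel,
    Superposition,
    kabsch_superpose,
)

__all__ = [
    "SYNTHETIC_TATPI_ORF",
    "SYNTHETIC_TATPI_TAG",
    "synthetic_construct_counts",
    "StudyDesign",
    "generate_auc_dataset",
    "generate_melt_curve",
    "default_melt_truth",
    "generate_toy_structures",
    "synthetic_reference_pair",
]

#: Synthetic stand-in for the 216-residue archaeal TPI ORF sequence.  The
#: real deposited sequence is not bundled; this surrogate was constructed
#: once to match the published composition-level anchors exactly: no Trp and
#: eight Tyr (eps280 = 11,920 with Pace coefficients, reduced Cys), nine
#: prolines (4.2% of 216), construct mass 24,671 Da with the His-tag below,
#: vbar(20 degC) ~= 0.7417 cm^3/g, and the catalytic / marker residues at
#: their author numbers (Lys9, Cys50, His89, Arg96, helix-5 segment
#: AEEAKYFREY at 106-115, Glu137, Gly143, Gly175, Ala196, Ser197).
SYNTHETIC_TATPI_ORF = (
    "MLLGSEPPKFTAVYLIKVIKDEARDYGEKLLIIIIQEETPLAPAASVIACSAGTLEATAE"
    "PYFNGQIKVAEAPSEVDCQAPGFGQIIAHKEKKIPRTLFQFQFIIAEEAKYFREYSKSLA"
    "TVFSGELEIFYKGKEAEVVDKTGKEIQLGQVKISEEAVYEGLDVTNRDDEATTFGDTLDE"
    "CLVPSGEVLLTGNIIASNYDTEGDIDARVILTKVGA"
)

#: C-terminal expression-tag of the construct (vector-encoded linker + His6).
SYNTHETIC_TATPI_TAG = "LEHHHHHH"

#: Helix-5 segment (author residues 106-115).
HELIX5_SEGMENT = "AEEAKYFREY"


def synthetic_construct_counts() -> ResidueCounts:
    """Composition of the synthetic expression construct (ORF + tag)."""
    return ResidueCounts.from_sequence(SYNTHETIC_TATPI_ORF, tag=SYNTHETIC_TATPI_TAG)


# ----------------------------------------------------------------------
# equilibrium AUC datasets
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Experimental design of the equilibrium-sedimentation study."""

    speeds_rpm: tuple[float, ...] = (20000.0, 26000.0)
    loading_uM: tuple[float, ...] = (12.6, 16.8, 21.0)
    monomer_mass: float = 24671.0
    eps280: float = 11920.0
    vbar: float = 0.7417
    density: float = 1.00704
    temperature_K: float = 293.15
    meniscus_cm: float = 6.9
    bottom_cm: float = 7.2
    points_per_scan: int = 130
    noise_sd: float = 0.005
    path_cm: float = 1.2

    def buoyancy(self) -> BuoyancyContext:
        return BuoyancyContext(vbar=self.vbar, density=self.density)

    def rotor(self, speed_rpm: float) -> RotorCondition:
        return RotorCondition(speed_rpm=speed_rpm, temperature_K=self.temperature_K,
                              meniscus_cm=self.meniscus_cm, bottom_cm=self.bottom_cm)


def _bottom_conc_from_loading(a0: float, am: float, rm: float, rb: float) -> float:
    """Bottom concentration conserving the sector-averaged loading signal a0.

    For C(r) = Cb exp[am (r^2 - rb^2)], mass conservation in a sector gives
    Cb = a0 (rb^2 - rm^2) am / (1 - exp[am (rm^2 - rb^2)]).
    """
    if abs(am) < 1e-12:
        return a0
    return a0 * (rb**2 - rm**2) * am / (1.0 - math.exp(am * (rm**2 - rb**2)))


def _column_average(model, ap: float, rm: float, rb: float) -> float:
    """Sector-averaged signal of a forward model (closed form per species)."""
    xm = rm**2 - rb**2
    scale = 2.0 / (rb**2 - rm**2)

    def species_avg(bottom: float, am: float) -> float:
        if abs(am) < 1e-12:
            return bottom
        return scale * bottom * (1.0 - math.exp(am * xm)) / (2.0 * am)

    if isinstance(model, HomogeneousModel):
        return species_avg(model.bottom_conc, ap * model.n * model.monomer_mass) + model.baseline
    am1 = ap * model.monomer_mass
    nmer_bottom = model.bottom_conc**model.n * math.exp(model.ln_k)
    return (species_avg(model.bottom_conc, am1)
            + species_avg(nmer_bottom, model.n * am1) + model.baseline)


def generate_auc_dataset(truth, design: StudyDesign = StudyDesign(),
                         seed: int = 0) -> list[RadialScan]:
    """Simulate one equilibrium run: every speed x loading combination.

    ``truth`` is a :class:`HomogeneousModel` or :class:`ReversibleModel`
    whose ``bottom_conc`` is ignored: each scan's bottom concentration is
    derived from its loading concentration by converting molar loading to
    absorbance (eps280, optical path) and conserving the column signal.
    Gaussian noise of sd ``design.noise_sd`` is added; the result is a pure
    function of (truth, design, seed).
    """
    if design.noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    rm, rb = design.meniscus_cm, design.bottom_cm
    radii = np.linspace(rm, rb, design.points_per_scan)
    scans = []
    for speed in design.speeds_rpm:
        rotor = design.rotor(speed)
        ap = reduced_buoyancy(design.buoyancy(), rotor)
        for conc in design.loading_uM:
            a0 = design.eps280 * conc * 1e-6 * design.path_cm
            if isinstance(truth, HomogeneousModel):
                am = ap * truth.n * truth.monomer_mass
                cb = _bottom_conc_from_loading(a0, am, rm, rb)
                model = HomogeneousModel(monomer_mass=truth.monomer_mass, n=truth.n,
                                         bottom_conc=cb, baseline=truth.baseline)
                signal = predict_homogeneous(model, ap, radii, rb)
            elif isinstance(truth, ReversibleModel):
                def mismatch(cb: float) -> float:
                    m = ReversibleModel(monomer_mass=truth.monomer_mass, n=truth.n,
                                        bottom_conc=cb, ln_k=truth.ln_k,
                                        baseline=truth.baseline)
                    return _column_average(m, ap, rm, rb) - a0 - truth.baseline
                cb = brentq(mismatch, 0.0, 10.0 * a0 * (rb**2 - rm**2)
                            * max(ap * truth.n * truth.monomer_mass, 1.0) + 10.0)
                model = ReversibleModel(monomer_mass=truth.monomer_mass, n=truth.n,
                                        bottom_conc=cb, ln_k=truth.ln_k,
                                        baseline=truth.baseline)
                signal = predict_reversible(model, ap, radii, rb)
            else:
                raise TypeError("truth must be a HomogeneousModel or ReversibleModel")
            noisy = signal + rng.normal(0.0, design.noise_sd, size=radii.size)
            scans.append(RadialScan(radii_cm=radii, absorbance=noisy, rotor=rotor,
                                    loading_uM=conc,
                                    sector=f"{speed:.0f}rpm/{conc:g}uM"))
    return scans


# ----------------------------------------------------------------------
# melt curves
# ----------------------------------------------------------------------

def default_melt_truth(td_C: float = 74.6) -> TwoStateParams:
    """Realistic truth for a theta-222 melt of a stable alpha/beta dimer."""
    return TwoStateParams(td_C=td_C, dh_vh_kJ_mol=450.0,
                          folded_intercept=-20.0, folded_slope=0.02,
                          unfolded_intercept=-4.0, unfolded_slope=0.01)


def generate_melt_curve(truth: TwoStateParams, grid_C: Sequence[float] | None = None,
                        noise_sd: float = 0.0, seed: int = 0) -> MeltCurve:
    """Two-state melt signal on a temperature grid, plus Gaussian noise.

    The grid must bracket the transition midpoint.
    """
    if grid_C is None:
        grid_C = np.arange(truth.td_C - 30.0, truth.td_C + 20.0 + 0.25, 0.5)
    t = np.asarray(grid_C, dtype=float)
    if not (t[0] < truth.td_C < t[-1]):
        raise ValueError("temperature grid does not bracket the transition midpoint")
    rng = np.random.default_rng(seed)
    signal = predict_signal(t, truth) + rng.normal(0.0, noise_sd, size=t.size)
    return MeltCurve(temperature_C=t, signal=signal, scan_rate_C_min=1.0)


# ----------------------------------------------------------------------
# toy and reference structures
# ----------------------------------------------------------------------

def generate_toy_structures(n_atoms: int = 50, perturbation_sd: float = 0.0,
                            rotation: np.ndarray | None = None,
                            translation: np.ndarray | None = None,
                            seed: int = 0):
    """Random coordinate cloud and a transformed, perturbed copy.

    Returns (fixed model, moving model, rotation, translation) where
    moving = R @ fixed + t + noise.  Useful for superposition recovery
    tests: with zero perturbation, Kabsch recovers (R, t) and RMSD 0.
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, 8.0, size=(n_atoms, 3))
    if rotation is None:
        rotation = _rotation_matrix(rng.uniform(0, 2 * math.pi, size=3))
    if translation is None:
        translation = rng.uniform(-20, 20, size=3)
    moved = coords @ np.asarray(rotation).T + np.asarray(translation)
    moved = moved + rng.normal(0.0, perturbation_sd, size=moved.shape)

    def as_model(xyz: np.ndarray, name: str) -> StructureModel:
        atoms = [Atom(chain="A", res_seq=i + 1, res_name="GLY", name="CA",
                      element="C", pos=xyz[i]) for i in range(xyz.shape[0])]
        return StructureModel(atoms, name=name)

    return (as_model(coords, "toy-fixed"), as_model(moved, "toy-moving"),
            np.asarray(rotation), np.asarray(translation))


def _rotation_matrix(euler_xyz: Sequence[float]) -> np.ndarray:
    ax, ay, az = euler_xyz
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


# residues that receive backbone-N and side-chain marker atoms
_SPECIAL_RESIDUES = (9, 89, 137, 143, 175, 196, 197)

#: Designed comparison geometry of the synthetic reference pair (Angstrom).
REFERENCE_GEOMETRY = {
    "ca_rmsd": 0.69,
    "loop6_marker": (143, 8.3),
    "loop7_marker": (175, 3.8),
    "carboxylate_contacts": {("OE1", "O1"): 2.65, ("OE2", "O2"): 2.70},
    "phosphate_contacts": {(143, "O1P"): 2.90, (175, "O2P"): 2.95,
                           (196, "O3P"): 3.05, (197, "O1P"): 2.88},
    "oxyanion_contacts": {(9, "NZ", "O2"): 2.85, (89, "NE2", "O2"): 2.80},
}


def _chain_scaffold(n_res: int) -> np.ndarray:
    """Smooth non-degenerate C-alpha curve (a solenoid), ~globular extent."""
    t = np.arange(n_res, dtype=float)
    phi = 2.0 * math.pi * t / n_res
    theta = 2.0 * math.pi * t / 7.2
    major, minor = 14.0, 6.0
    x = (major + minor * np.cos(theta)) * np.cos(phi)
    y = (major + minor * np.cos(theta)) * np.sin(phi)
    z = minor * np.sin(theta) + 0.02 * t
    return np.stack([x, y, z], axis=1)


def _ligand_atoms_local(center: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized glycerol-3-phosphate-like atom layout around a center."""
    L = center
    atoms = {
        "C1": L + [0.5, 0.5, 0.0], "O1": L + [1.2, -0.6, 0.4],
        "C2": L + [-0.7, 0.9, 0.2], "O2": L + [-1.4, -0.5, 0.6],
        "C3": L + [0.1, 1.8, -0.5], "P": L + [0.0, -2.2, -0.3],
    }
    atoms["O1P"] = atoms["P"] + [1.2, -0.7, 0.3]
    atoms["O2P"] = atoms["P"] + [-1.1, -0.8, 0.2]
    atoms["O3P"] = atoms["P"] + [0.1, -0.5, 1.4]
    return atoms


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def synthetic_reference_pair(seed: int = 20150, n_chains: int = 4):
    """Synthetic stand-in for the apo / ligand-bound crystal-structure pair.

    Builds two four-chain models of the 216-residue synthetic TPI sequence:
    an apo form and a ligand-bound form whose chains differ by a calibrated
    displacement field embodying the published open-to-closed geometry: the
    per-chain C-alpha RMSD after superposition equals
    ``REFERENCE_GEOMETRY["ca_rmsd"]``; the loop-6 marker (Gly143) and loop-7
    marker (Gly175) move 8.3 and 3.8 A toward the ligand; the catalytic
    glutamate carboxylate sits within 3 A of the ligand O1/O2, and the
    ligand phosphate oxygens sit within 3.5 A of the backbone nitrogens of
    residues 143, 175, 196 and 197.  These are idealized marker coordinates
    (no full side chains, no stereochemistry) intended for testing geometry
    code, not for any structural inference.

    Returns (apo, bound) StructureModel objects.
    """
    seq = SYNTHETIC_TATPI_ORF
    n_res = len(seq)
    rng = np.random.default_rng(seed)
    apo_ca = _chain_scaffold(n_res)

    # provisional ligand center from the active-site marker residues
    idx = {r: r - 1 for r in _SPECIAL_RESIDUES}
    center = apo_ca[[idx[r] for r in (9, 89, 137, 196, 197)]].mean(axis=0)
    center = center + np.array([0.0, 0.0, 2.0])

    # displacement field: designed loop displacements toward the ligand plus
    # an isotropic background scaled to reach the designed global RMSD
    d_loop = np.zeros((n_res, 3))
    for res, dist in (REFERENCE_GEOMETRY["loop6_marker"],
                      REFERENCE_GEOMETRY["loop7_marker"]):
        d_loop[res - 1] = dist * _unit(center - apo_ca[res - 1])
    for res, dist in ((142, 2.0), (144, 2.0), (174, 1.5), (176, 1.5)):
        d_loop[res - 1] = dist * _unit(center - apo_ca[res - 1])
    d_bg = rng.normal(0.0, 1.0, size=(n_res, 3))
    d_bg[np.any(d_loop != 0.0, axis=1)] = 0.0

    target = REFERENCE_GEOMETRY["ca_rmsd"]

    def rmsd_at(alpha: float) -> float:
        return kabsch_superpose(apo_ca, apo_ca + d_loop + alpha * d_bg).rmsd

    if rmsd_at(0.0) > target:
        raise RuntimeError("designed loop displacements alone exceed the target RMSD")
    alpha = brentq(lambda a: rmsd_at(a) - target, 0.0, 5.0, xtol=1e-10)
    bound_ca = apo_ca + d_loop + alpha * d_bg

    # ligand placed relative to the bound (closed) conformation
    lig = _ligand_atoms_local(center)

    # marker atoms at designed distances from ligand atoms, pointing
    # radially outward from the ligand cluster so they cannot land inside it
    lig_centroid = np.mean(list(lig.values()), axis=0)

    def marker(res: int, lig_atom: str, dist: float) -> np.ndarray:
        outward = _unit(lig[lig_atom] - lig_centroid)
        return lig[lig_atom] + dist * outward

    bound_extra: dict[tuple[int, str], np.ndarray] = {}
    geo = REFERENCE_GEOMETRY
    bound_extra[(137, "OE1")] = marker(137, "O1", geo["carboxylate_contacts"][("OE1", "O1")])
    bound_extra[(137, "OE2")] = marker(137, "O2", geo["carboxylate_contacts"][("OE2", "O2")])
    for (res, lig_atom), dist in geo["phosphate_contacts"].items():
        bound_extra[(res, "N")] = marker(res, lig_atom, dist)
    for (res, atom, lig_atom), dist in geo["oxyanion_contacts"].items():
        bound_extra[(res, atom)] = marker(res, lig_atom, dist)
    # backbone N for the remaining special residues, near their C-alpha
    for res in _SPECIAL_RESIDUES:
        if (res, "N") not in bound_extra:
            bound_extra[(res, "N")] = bound_ca[res - 1] + np.array([0.8, 0.9, 0.5])
    # a stub CB->CD arm for the catalytic glutamate
    for frac, name in ((0.3, "CB"), (0.55, "CG"), (0.8, "CD")):
        bound_extra[(137, name)] = (bound_ca[136] * (1 - frac)
                                    + bound_extra[(137, "OE1")] * frac)

    # apo gets the same extra atoms rigidly attached to its own C-alphas
    apo_extra = {(res, name): apo_ca[res - 1] + (pos - bound_ca[res - 1])
                 for (res, name), pos in bound_extra.items()}

    element_of = {"N": "N", "NZ": "N", "NE2": "N", "OE1": "O", "OE2": "O",
                  "CB": "C", "CG": "C", "CD": "C"}

    def chain_atoms(chain_id: str, ca: np.ndarray, extra: dict,
                    transform) -> list[Atom]:
        atoms = []
        for i in range(n_res):
            atoms.append(Atom(chain=chain_id, res_seq=i + 1,
                              res_name=ONE_TO_THREE[seq[i]], name="CA",
                              element="C", pos=transform(ca[i])))
        for (res, name), pos in sorted(extra.items()):
            atoms.append(Atom(chain=chain_id, res_seq=res,
                              res_name=ONE_TO_THREE[seq[res - 1]], name=name,
                              element=element_of[name], pos=transform(pos)))
        return atoms

    def assembly_transforms(global_rot: np.ndarray, global_t: np.ndarray):
        out = []
        for j in range(n_chains):
            rot = _rotation_matrix([0.0, 0.0, j * math.pi / 2.0])
            shift = np.array([46.0 * (j % 2), 46.0 * (j // 2), 0.0])
            out.append(lambda p, r=rot, s=shift: global_rot @ (r @ p + s) + global_t)
        return out

    chain_ids = "ABCD"[:n_chains]
    apo_atoms: list[Atom] = []
    ident = np.eye(3)
    for cid, tr in zip(chain_ids, assembly_transforms(ident, np.zeros(3))):
        apo_atoms.extend(chain_atoms(cid, apo_ca, apo_extra, tr))

    # the bound crystal sits in a different frame: arbitrary rigid transform
    grot = _rotation_matrix([0.4, -0.7, 1.9])
    gt = np.array([11.0, -7.0, 23.0])
    bound_atoms: list[Atom] = []
    for cid, tr in zip(chain_ids, assembly_transforms(grot, gt)):
        bound_atoms.extend(chain_atoms(cid, bound_ca, bound_extra, tr))
        for name, pos in lig.items():
            bound_atoms.append(Atom(chain=cid, res_seq=301, res_name="G3P",
                                    name=name, element=("P" if name == "P" else
                                                        "O" if name.startswith("O") else "C"),
                                    pos=tr(pos), hetero=True))

    apo = StructureModel(apo_atoms, name="synthetic-apo")
    bound = StructureModel(bound_atoms, name="synthetic-ligand-bound")
    return apo, bound
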