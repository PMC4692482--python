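"""Quantitative comparison of atomic structures.

Rigid-body (Kabsch) superposition, C-alpha RMSD over residue mappings,
per-residue displacement between two conformers, protein--ligand contact
tables, and simple sequence metrics (proline content, mean hydrophobicity of
a segment).  These are the measurements used to characterise a
ligand-induced open-to-closed transition: the global backbone agreement, how
far the active-site loops move, and which protein atoms coordinate the
ligand.

Coordinates are in Angstrom in the deposited frame.  Residues are identified
by (chain id, author residue number, insertion code).  Alternate locations
are resolved to the highest-occupancy conformer (ties toward altloc 'A')
when a file is read; waters are excluded from superpositions and contact
searches unless selected explicitly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from ._tables import HYDROPHOBICITY_SCALES

__all__ = [
    "Atom",
    "StructureModel",
    "Superposition",
    "Selection",
    "Contact",
    "read_structure",
    "write_pdb",
    "kabsch_superpose",
    "build_ca_mapping",
    "ca_rmsd",
    "all_chain_pair_ca_rmsd",
    "residue_displacement",
    "contact_distances",
    "proline_fraction",
    "segment_hydrophobicity",
]

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One atom with its author-numbering identity and position (Angstrom)."""

    chain: str
    res_seq: int
    res_name: str
    name: str
    element: str
    pos: np.ndarray
    icode: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    hetero: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.pos, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"atom {self.chain}/{self.res_seq}/{self.name} "
                             "needs a finite 3-vector position")
        object.__setattr__(self, "pos", p)


class StructureModel:
    """Parsed atomic model: atoms, per-chain polymer sequences, hetero groups."""

    def __init__(self, atoms: Sequence[Atom], name: str = "model"):
        self.name = name
        self.atoms: list[Atom] = list(atoms)
        keys = [(a.chain, a.res_seq, a.icode, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate atom keys; resolve altlocs before constructing")

    # -- views -----------------------------------------------------------
    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def polymer_sequence(self, chain: str) -> str:
        """One-letter sequence of the standard amino acid residues in a chain."""
        residues: dict[tuple[int, str], str] = {}
        for a in self.atoms:
            if a.chain == chain and not a.hetero and a.res_name in THREE_TO_ONE:
                residues[(a.res_seq, a.icode)] = THREE_TO_ONE[a.res_name]
        return "".join(residues[k] for k in sorted(residues))

    def hetero_groups(self) -> list[tuple[str, int, str]]:
        """(chain, residue number, residue name) of non-water hetero groups."""
        out: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            if a.hetero and a.res_name not in WATER_NAMES:
                out.setdefault((a.chain, a.res_seq, a.res_name), None)
        return list(out)

    def get_atom(self, chain: str, res_seq: int, name: str, icode: str = "") -> Atom:
        for a in self.atoms:
            if (a.chain, a.res_seq, a.icode, a.name) == (chain, res_seq, icode, name):
                return a
        raise KeyError(f"atom {name} of residue {chain}{res_seq}{icode} not found")

    def ca_table(self, chain: str) -> dict[tuple[int, str], Atom]:
        return {(a.res_seq, a.icode): a for a in self.atoms
                if a.chain == chain and a.name == "CA" and not a.hetero
                and a.res_name in THREE_TO_ONE}


def _resolve_altlocs(atoms: Iterable[Atom]) -> list[Atom]:
    best: dict[tuple, Atom] = {}
    for a in atoms:
        key = (a.chain, a.res_seq, a.icode, a.name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
        elif (a.occupancy, -ord(a.altloc or "z")) > (cur.occupancy, -ord(cur.altloc or "z")):
            best[key] = a
    return [Atom(chain=a.chain, res_seq=a.res_seq, res_name=a.res_name, name=a.name,
                 element=a.element, pos=a.pos, icode=a.icode, altloc="",
                 occupancy=a.occupancy, hetero=a.hetero) for a in best.values()]


def read_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only).

    The format is inferred from the extension unless given as ``"pdb"`` or
    ``"cif"``.  Alternate locations are resolved to the highest-occupancy
    conformer.  Parse anomalies that gemmi can recover from are logged.
    """
    path = str(path)
    if fmt is None:
        st = gemmi.read_structure(path)
    else:
        coor_format = {"pdb": gemmi.CoorFormat.Pdb,
                       "cif": gemmi.CoorFormat.Mmcif,
                       "mmcif": gemmi.CoorFormat.Mmcif}[fmt.lower()]
        st = gemmi.read_structure(path, format=coor_format)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if len(st) > 1:
        logger.info("%s has %d models; using the first", path, len(st))
    atoms: list[Atom] = []
    for chain in st[0]:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(Atom(chain=chain.name, res_seq=res.seqid.num,
                                  res_name=res.name, name=at.name,
                                  element=at.element.name, pos=np.array(at.pos.tolist()),
                                  icode=res.seqid.icode.strip(), altloc=at.altloc,
                                  occupancy=at.occ, hetero=het))
    return StructureModel(_resolve_altlocs(atoms), name=st.name or path)


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel to a PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = model.name
    md = gemmi.Model("1")
    for chain_id in model.chains:
        ch = gemmi.Chain(chain_id)
        current = None
        res = None
        for a in model.atoms:
            if a.chain != chain_id:
                continue
            key = (a.res_seq, a.icode, a.res_name)
            if key != current:
                res = gemmi.Residue()
                res.name = a.res_name
                res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
                res.het_flag = "H" if a.hetero else "A"
                ch.add_residue(res)
                current = key
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.pos)
            at.occ = a.occupancy
            ch[-1].add_atom(at)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# -- superposition -------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform mapping a moving set onto a fixed set."""

    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # applied after rotation
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(fixed: np.ndarray, moving: np.ndarray) -> Superposition:
    """Optimal rigid-body superposition (Kabsch, via SVD).

    Returns the rotation/translation minimising the RMSD of
    ``apply(moving)`` against ``fixed``.  Degenerate (collinear) point sets
    are rejected.
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(moving, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need two equal-shape (n>=3, 3) coordinate arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=P.shape[0])


def build_ca_mapping(model_a: StructureModel, model_b: StructureModel,
                     chain_a: str, chain_b: str) -> list[tuple[tuple, tuple]]:
    """Same-residue-number, same-residue-type C-alpha mapping of two chains.

    Residues missing a C-alpha on either side are dropped with a warning.
    """
    ca_a = model_a.ca_table(chain_a)
    ca_b = model_b.ca_table(chain_b)
    common = sorted(set(ca_a) & set(ca_b))
    pairs = []
    for key in common:
        if ca_a[key].res_name != ca_b[key].res_name:
            continue
        pairs.append(((chain_a, *key), (chain_b, *key)))
    dropped = len(set(ca_a) ^ set(ca_b))
    if dropped:
        warnings.warn(f"{dropped} residues lack a mapped C-alpha in "
                      f"{chain_a}/{chain_b} and were dropped", stacklevel=2)
    return pairs


@dataclass(frozen=True)
class CaRmsdResult:
    rmsd: float
    n_atoms: int
    superposition: Superposition


def ca_rmsd(model_a: StructureModel, model_b: StructureModel,
            mapping: Sequence[tuple[tuple, tuple]]) -> CaRmsdResult:
    """C-alpha RMSD after optimal superposition over a residue mapping.

    ``mapping`` pairs residue keys ``(chain, res_seq[, icode])`` of model A
    with keys of model B.
    """
    if not mapping:
        raise ValueError("empty residue mapping")
    coords_a, coords_b = [], []
    for key_a, key_b in mapping:
        ka = (key_a + ("",))[:3]
        kb = (key_b + ("",))[:3]
        coords_a.append(model_a.get_atom(ka[0], ka[1], "CA", ka[2]).pos)
        coords_b.append(model_b.get_atom(kb[0], kb[1], "CA", kb[2]).pos)
    sup = kabsch_superpose(np.array(coords_a), np.array(coords_b))
    return CaRmsdResult(rmsd=sup.rmsd, n_atoms=len(mapping), superposition=sup)


def all_chain_pair_ca_rmsd(model_a: StructureModel, model_b: StructureModel):
    """C-alpha RMSD for every protein chain pairing of two models.

    Returns a list of dict rows (chain_a, chain_b, rmsd, n_atoms) sorted by
    RMSD; feed into pandas for reporting.
    """
    rows = []
    for ca, cb in itertools.product(model_a.chains, model_b.chains):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mapping = build_ca_mapping(model_a, model_b, ca, cb)
        if len(mapping) < 3:
            continue
        res = ca_rmsd(model_a, model_b, mapping)
        rows.append({"chain_a": ca, "chain_b": cb,
                     "rmsd": res.rmsd, "n_atoms": res.n_atoms})
    return sorted(rows, key=lambda r: r["rmsd"])


def residue_displacement(model_a: StructureModel, model_b: StructureModel,
                         superposition: Superposition, chain: str, res_seq: int,
                         atom_name: str = "CA", chain_b: str | None = None,
                         res_seq_b: int | None = None) -> float:
    """Distance (Angstrom) between an atom of model A and the superposed
    equivalent atom of model B.

    ``superposition`` must map model B coordinates into the model A frame
    (e.g. from :func:`ca_rmsd` with model A fixed).
    """
    atom_a = model_a.get_atom(chain, res_seq, atom_name)
    atom_b = model_b.get_atom(chain_b or chain, res_seq_b or res_seq, atom_name)
    moved = superposition.apply(atom_b.pos[None, :])[0]
    return float(np.linalg.norm(atom_a.pos - moved))


# -- contacts ------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Atom selection by chain / residue name / residue number / atom names."""

    chain: str | None = None
    res_name: str | None = None
    res_seq: int | None = None
    atom_names: tuple[str, ...] | None = None
    hetero: bool | None = None

    def matches(self, atom: Atom) -> bool:
        if atom.res_name in WATER_NAMES and self.res_name not in WATER_NAMES:
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.res_name is not None and atom.res_name != self.res_name:
            return False
        if self.res_seq is not None and atom.res_seq != self.res_seq:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.hetero is not None and atom.hetero != self.hetero:
            return False
        return True


@dataclass(frozen=True)
class Contact:
    protein_atom: tuple[str, int, str, str]   # chain, res_seq, res_name, atom
    ligand_atom: tuple[str, int, str, str]
    distance: float


def contact_distances(model: StructureModel, ligand: Selection,
                      protein: Selection, cutoff: float = 3.5) -> list[Contact]:
    """All protein-ligand atom pairs within ``cutoff`` Angstrom, sorted by distance."""
    lig_atoms = [a for a in model.atoms if ligand.matches(a)]
    if not lig_atoms:
        warnings.warn("ligand selection matched no atoms", stacklevel=2)
        return []
    prot_atoms = [a for a in model.atoms if protein.matches(a)]
    out = []
    for pa in prot_atoms:
        for la in lig_atoms:
            d = float(np.linalg.norm(pa.pos - la.pos))
            if d <= cutoff:
                out.append(Contact(
                    protein_atom=(pa.chain, pa.res_seq, pa.res_name, pa.name),
                    ligand_atom=(la.chain, la.res_seq, la.res_name, la.name),
                    distance=d))
    return sorted(out, key=lambda c: c.distance)


# -- sequence metrics ----------------------------------------------------

def proline_fraction(sequence: str) -> float:
    """Proline content of a one-letter sequence in percent, to one decimal."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(THREE_TO_ONE.values())
    if bad:
        raise ValueError(f"non-standard residue codes: {sorted(bad)}")
    return round(100.0 * seq.count("P") / len(seq), 1)


def segment_hydrophobicity(segment: str, scale: str = "eisenberg-consensus") -> float:
    """Mean per-residue hydrophobicity of a segment on a named scale."""
    if not segment:
        raise ValueError("empty segment")
    try:
        table = HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ValueError(f"unknown hydrophobicity scale {scale!r}") from None
    vals = []
    for aa in segment.upper():
        if aa not in table:
            raise ValueError(f"residue {aa!r} not in scale {scale!r}")
        vals.append(table[aa])
    return float(np.mean(vals))
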