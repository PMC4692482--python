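"""Structure parsing, superposition, contacts and sequence metrics."""

import numpy as np
import pytest

from tpistab.structure import (
    Atom,
    Selection,
    StructureModel,
    build_ca_mapping,
    ca_rmsd,
    contact_distances,
    kabsch_superpose,
    proline_fraction,
    read_structure,
    residue_displacement,
    segment_hydrophobicity,
    write_pdb,
)
from tpistab.synth import generate_toy_structures

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.759   7.113  -4.973  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1      10.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1      20.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       0.000   1.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_fixture_round_trip(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_structure(path)
        assert len(model.atoms) == 3
        assert model.chains == ["A"]
        assert model.polymer_sequence("A") == "A"

    def test_altloc_highest_occupancy_retained(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path)
        ca = model.get_atom("A", 1, "CA")
        assert ca.pos[0] == pytest.approx(10.0)  # occupancy 0.6 conformer
        assert len(model.atoms) == 2

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(Exception):
            read_structure(tmp_path / "absent.pdb")

    def test_write_read_round_trip_preserves_content(self, tmp_path, reference_pair):
        _, bound = reference_pair
        path = tmp_path / "bound.pdb"
        write_pdb(bound, path)
        back = read_structure(path)
        assert set(back.chains) == set(bound.chains)
        assert back.polymer_sequence("A") == bound.polymer_sequence("A")
        het = back.hetero_groups()
        assert ("A", 301, "G3P") in het

    def test_bound_model_has_ligand_and_four_chains(self, reference_pair):
        _, bound = reference_pair
        assert len(bound.chains) == 4
        names = {name for _, _, name in bound.hetero_groups()}
        assert names == {"G3P"}


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch_superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_pure_translation_recovered(self):
        coords = np.random.default_rng(1).normal(size=(8, 3))
        t = np.array([3.0, -2.0, 7.0])
        sup = kabsch_superpose(coords, coords + t)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.translation, -t, atol=1e-10)

    def test_matches_rotation_grid_search_oracle(self):
        """Brute-force search over rotations agrees to 3 decimals on a
        4-point set with one perturbed point."""
        fixed = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 1.9, 2.7]])
        angles = np.radians([25.0, -40.0, 65.0])
        moving = fixed @ _euler(angles).T + np.array([1.0, -2.0, 0.5])
        moving[2] += np.array([0.7, -0.3, 0.4])
        sup = kabsch_superpose(fixed, moving)

        f0 = fixed - fixed.mean(0)

        def rmsd_at(angles):
            Q = moving @ _euler(angles).T
            diff = (Q - Q.mean(0)) - f0   # optimal translation removed
            return np.sqrt(np.mean(np.sum(diff**2, axis=1)))

        # global coarse grid, then hierarchical refinement
        coarse = np.linspace(-np.pi, np.pi, 25)
        best, centre = np.inf, np.zeros(3)
        for a in coarse:
            for b in coarse:
                for c in coarse:
                    r = rmsd_at([a, b, c])
                    if r < best:
                        best, centre = r, np.array([a, b, c])
        step = coarse[1] - coarse[0]
        for _ in range(7):
            best_angles = centre
            for da in np.linspace(-step, step, 7):
                for db in np.linspace(-step, step, 7):
                    for dc in np.linspace(-step, step, 7):
                        r = rmsd_at(centre + [da, db, dc])
                        if r < best:
                            best, best_angles = r, centre + [da, db, dc]
            centre = best_angles
            step /= 3.0
        assert sup.rmsd == pytest.approx(best, abs=1e-3)

    def test_optimality_beats_identity_transform(self):
        fixed, moving, _, _ = generate_toy_structures(30, perturbation_sd=0.8, seed=5)
        f = np.array([a.pos for a in fixed.atoms])
        m = np.array([a.pos for a in moving.atoms])
        sup = kabsch_superpose(f, m)
        identity_rmsd = np.sqrt(np.mean(np.sum((m - f) ** 2, axis=1)))
        assert sup.rmsd <= identity_rmsd + 1e-12

    def test_collinear_sets_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)


class TestCaRmsd:
    def test_model_vs_itself_is_zero(self, reference_pair):
        apo, _ = reference_pair
        mapping = build_ca_mapping(apo, apo, "A", "A")
        assert ca_rmsd(apo, apo, mapping).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_rigid_invariant(self, reference_pair):
        apo, bound = reference_pair
        mapping = build_ca_mapping(apo, bound, "A", "A")
        forward = ca_rmsd(apo, bound, mapping).rmsd
        backward = ca_rmsd(bound, apo, [(b, a) for a, b in mapping]).rmsd
        assert forward == pytest.approx(backward, abs=1e-9)

    def test_single_displaced_atom_hand_rmsd(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=9.0, size=(40, 3))
        atoms_a = [Atom("A", i + 1, "GLY", "CA", "C", coords[i]) for i in range(40)]
        moved = coords.copy()
        moved[7] += np.array([1.0, 0.0, 0.0])
        atoms_b = [Atom("A", i + 1, "GLY", "CA", "C", moved[i]) for i in range(40)]
        model_a, model_b = StructureModel(atoms_a), StructureModel(atoms_b)
        # superposition from the 39 unmoved residues is the identity
        anchor = [(("A", i + 1), ("A", i + 1)) for i in range(40) if i != 7]
        sup = ca_rmsd(model_a, model_b, anchor).superposition
        d = residue_displacement(model_a, model_b, sup, "A", 8)
        # hand value: the displaced atom sits 1 A away, its neighbour 0 A
        assert d == pytest.approx(1.0, abs=0.01)
        assert np.sqrt((d**2 + 0.0) / 2.0) == pytest.approx(np.sqrt(0.5), abs=0.01)

    def test_missing_ca_dropped_with_warning(self, reference_pair):
        apo, bound = reference_pair
        trimmed = StructureModel([a for a in apo.atoms
                                  if not (a.chain == "A" and a.res_seq == 5)],
                                 name="trimmed")
        with pytest.warns(UserWarning, match="dropped"):
            mapping = build_ca_mapping(trimmed, bound, "A", "A")
        assert len(mapping) == 215


class TestContacts:
    def test_cutoff_nesting(self, reference_pair):
        _, bound = reference_pair
        lig = Selection(chain="A", res_name="G3P")
        prot = Selection(chain="A", hetero=False)
        close = contact_distances(bound, lig, prot, cutoff=3.0)
        wide = contact_distances(bound, lig, prot, cutoff=3.5)
        close_keys = {(c.protein_atom, c.ligand_atom) for c in close}
        wide_keys = {(c.protein_atom, c.ligand_atom) for c in wide}
        assert close_keys <= wide_keys
        assert all(a.distance <= b.distance for a, b in zip(close, close[1:]))

    def test_empty_ligand_selection_warns(self, reference_pair):
        apo, _ = reference_pair
        with pytest.warns(UserWarning, match="no atoms"):
            out = contact_distances(apo, Selection(res_name="G3P"),
                                    Selection(chain="A"))
        assert out == []

    def test_absent_atom_error_names_residue(self, reference_pair):
        apo, _ = reference_pair
        with pytest.raises(KeyError, match="A10"):
            apo.get_atom("A", 10, "NZ")


class TestSequenceMetrics:
    def test_all_proline(self):
        assert proline_fraction("PPPP") == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            proline_fraction("")

    def test_nonstandard_code_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            proline_fraction("ACDX")

    def test_single_residue_hydrophobicity_is_table_value(self):
        assert segment_hydrophobicity("I") == pytest.approx(0.73)

    def test_helix5_segment_hand_average(self):
        # hand sum of the ten scale values / 10
        value = segment_hydrophobicity("AEEAKYFREY")
        assert value == pytest.approx(-0.357, abs=1e-9)
        assert segment_hydrophobicity("LLLLL") > value

    def test_poly_leu_more_hydrophobic_than_poly_glu(self):
        assert segment_hydrophobicity("LLLL") > segment_hydrophobicity("EEEE")

    def test_unknown_scale_or_residue_rejected(self):
        with pytest.raises(ValueError):
            segment_hydrophobicity("AAA", scale="nope")
        with pytest.raises(ValueError):
            segment_hydrophobicity("AZ")


def _euler(angles):
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx
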