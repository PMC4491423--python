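import numpy as np
import pytest

from hemocharge import surface as surf
from hemocharge.io import AlignmentRecord, Atom, MultipleAlignment, ProteinStructure, Residue
from hemocharge.simulate import (
    dimer_analytic_sasa,
    generate_toy_structure,
    isolated_sphere_sasa,
)


def carbon_structure(coords):
    atoms = [Atom("CA", "C", *xyz, 1.70) for xyz in coords]
    return ProteinStructure([Residue("A", i + 1, "ALA", [a]) for i, a in enumerate(atoms)])


class TestGoldenSpiral:
    def test_points_on_unit_sphere(self):
        pts = surf.golden_spiral_points(500)
        assert pts.shape == (500, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_quasi_uniform_centroid_near_origin(self):
        pts = surf.golden_spiral_points(960)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestShrakeRupley:
    def test_isolated_carbon_matches_sphere_area(self):
        s = generate_toy_structure("single_atom")
        areas, table = surf.shrake_rupley_sasa(s)
        exact = isolated_sphere_sasa(1.70)  # 4*pi*3.10^2
        assert exact == pytest.approx(120.76, abs=0.01)
        assert areas[0] == pytest.approx(exact, rel=0.02)

    def test_distant_dimer_each_atom_isolated(self):
        s = generate_toy_structure("dimer", separation=7.0)  # > 2*(1.7+1.4)
        areas, _ = surf.shrake_rupley_sasa(s)
        exact = isolated_sphere_sasa(1.70)
        assert np.allclose(areas, exact, rtol=0.02)

    @pytest.mark.parametrize("separation", [2.0, 3.0, 4.0, 5.0])
    def test_overlapping_dimer_matches_spherical_cap_oracle(self, separation):
        s = generate_toy_structure("dimer", separation=separation)
        areas, _ = surf.shrake_rupley_sasa(s, n_points=1920)
        exact = dimer_analytic_sasa(1.70, separation)
        assert areas[0] == pytest.approx(exact, rel=0.02)
        assert areas[1] == pytest.approx(exact, rel=0.02)

    def test_rotation_translation_invariance(self):
        # tolerance is set by the sphere-point resolution, so check at a
        # sampling fine enough for occluded atoms (their areas are ~25 A^2)
        n_points = 7680
        s = generate_toy_structure("helix", n_residues=10)
        areas, _ = surf.shrake_rupley_sasa(s, n_points=n_points)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = ProteinStructure(
            [
                Residue(
                    r.chain,
                    r.number,
                    r.name,
                    [
                        Atom(a.name, a.element, *(rot @ a.coord + np.array([5.0, -3.0, 2.0])), a.radius)
                        for a in r.atoms
                    ],
                )
                for r in s.residues
            ]
        )
        areas2, _ = surf.shrake_rupley_sasa(moved, n_points=n_points)
        assert np.max(np.abs(areas - areas2) / np.maximum(areas, 1.0)) < 0.005

    def test_total_sasa_monotone_under_atom_addition(self):
        base = carbon_structure([(0, 0, 0), (2.5, 0, 0)])
        bigger = carbon_structure([(0, 0, 0), (2.5, 0, 0), (1.2, 2.0, 0)])
        a1, _ = surf.shrake_rupley_sasa(base)
        a2, _ = surf.shrake_rupley_sasa(bigger)
        assert a2[0] <= a1[0] + 1e-9
        assert a2[1] <= a1[1] + 1e-9

    def test_point_count_convergence(self):
        s = generate_toy_structure("helix", n_residues=8)
        a1, _ = surf.shrake_rupley_sasa(s, n_points=1920)
        a2, _ = surf.shrake_rupley_sasa(s, n_points=3840)
        nonzero = a1 > 1.0
        assert np.max(np.abs(a1[nonzero] - a2[nonzero]) / a1[nonzero]) < 0.01

    def test_shell_encloses_centre_completely(self):
        s = generate_toy_structure("shell")
        areas, table = surf.shrake_rupley_sasa(s)
        assert areas[0] == 0.0

    def test_too_few_points_rejected(self):
        s = generate_toy_structure("single_atom")
        with pytest.raises(ValueError):
            surf.shrake_rupley_sasa(s, n_points=50)


class TestExposureClassification:
    def test_isolated_residue_exposed(self):
        s = generate_toy_structure("single_atom")
        prof = surf.exposure_profile(s)
        assert prof.table.exposure.iloc[0] == "exposed"

    def test_shell_centre_buried(self):
        s = generate_toy_structure("shell")
        prof = surf.exposure_profile(s)
        centre = prof.table[prof.table.residue_number == 1]
        assert centre.exposure.iloc[0] == "buried"

    def test_unknown_residue_type_errors(self):
        s = ProteinStructure([Residue("A", 1, "XYZ", [Atom("CA", "C", 0, 0, 0, 1.7)])])
        _, table = surf.shrake_rupley_sasa(s)
        with pytest.raises(ValueError, match="XYZ"):
            surf.classify_exposure(table)

    def test_helix_yields_mixed_classes(self):
        s = generate_toy_structure("helix", n_residues=12)
        prof = surf.exposure_profile(s)
        assert prof.table.exposure.nunique() >= 2

    def test_agrees_with_independent_sasa_implementation(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        s = generate_toy_structure("helix", n_residues=10)
        areas, _ = surf.shrake_rupley_sasa(s, n_points=1920)
        arr = biotite_struc.AtomArray(len(s.atoms))
        arr.coord = np.array([a.coord for a in s.atoms])
        arr.element = np.array([a.element for a in s.atoms])
        arr.res_id = np.arange(1, len(s.atoms) + 1)
        arr.atom_name = np.array(["CA"] * len(s.atoms))
        arr.res_name = np.array(["ALA"] * len(s.atoms))
        arr.chain_id = np.array(["A"] * len(s.atoms))
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=1000,
                                 vdw_radii="Single")
        # biotite's single-atom radii differ slightly from ours; compare loosely
        assert np.corrcoef(areas, ref)[0, 1] > 0.99


def protein_fragment(seq, start=1):
    return MultipleAlignment(
        records=[AlignmentRecord("ref_1", "ref", "1", seq)],
        alphabet="protein",
        canonical_start=start,
    )


def structure_from_sequence(seq, spacing=3.9):
    from Bio.Data.IUPACData import protein_letters_1to3

    residues = []
    for i, aa in enumerate(seq):
        name = protein_letters_1to3[aa].upper()
        residues.append(
            Residue("A", i + 1, name, [Atom("CA", "C", i * spacing, 0.0, 0.0, 1.70)])
        )
    return ProteinStructure(residues)


class TestResidueMapping:
    SEQ = "MKEHALDEVWKEY"

    def test_identical_sequence_identity_mapping(self):
        frag = protein_fragment(self.SEQ, start=100)
        structure = structure_from_sequence(self.SEQ)
        mapping = surf.map_alignment_to_structure(frag, structure)
        assert mapping.identity == pytest.approx(1.0)
        assert mapping.structure_residue(100) == ("A", 1)
        assert mapping.structure_residue(112) == ("A", 13)

    def test_internal_deletion_skips_exactly_one_residue(self):
        deleted = self.SEQ[:5] + self.SEQ[6:]  # drop residue 6
        frag = protein_fragment(deleted, start=100)
        structure = structure_from_sequence(self.SEQ)
        mapping = surf.map_alignment_to_structure(frag, structure)
        mapped_struct = {v[1] for v in mapping.canonical_to_structure.values()}
        assert 6 not in mapped_struct
        assert len(mapping.canonical_to_structure) == len(deleted)

    def test_low_identity_rejected_as_wrong_structure(self):
        frag = protein_fragment("WWWWWWWWWWWWW", start=1)
        structure = structure_from_sequence("MKEHALDEVAKEY")
        with pytest.raises(ValueError, match="identity"):
            surf.map_alignment_to_structure(frag, structure, min_identity=0.5)

    def test_homologous_fragment_maps_with_mismatches(self):
        # paralog-level similarity: several substitutions but same length
        frag = protein_fragment("MKDHALEEVWKDY", start=50)
        structure = structure_from_sequence(self.SEQ)
        mapping = surf.map_alignment_to_structure(frag, structure, min_identity=0.5)
        assert len(mapping.canonical_to_structure) == 13
        assert mapping.identity < 1.0


class TestMinDistance:
    def test_identical_selection_zero(self):
        a = np.array([[1.0, 2.0, 3.0]])
        assert surf.min_distance(a, a) == 0.0

    def test_pythagorean_triple(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[3.0, 4.0, 0.0]])
        assert surf.min_distance(a, b) == pytest.approx(5.0)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        x, y, z = (rng.normal(size=(1, 3)) for _ in range(3))
        assert surf.min_distance(x, y) == pytest.approx(surf.min_distance(y, x))
        assert surf.min_distance(x, z) <= surf.min_distance(x, y) + surf.min_distance(y, z) + 1e-12

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            surf.min_distance(np.empty((0, 3)), np.array([[0.0, 0.0, 0.0]]))

    def test_select_atoms_filters(self):
        s = structure_from_sequence("MKE")
        sel = surf.select_atoms(s, residue_numbers=[2], atom_names=["CA"])
        assert sel.shape == (1, 3)
        assert surf.min_distance(
            surf.select_atoms(s, residue_numbers=[1]), surf.select_atoms(s, residue_numbers=[3])
        ) == pytest.approx(7.8)
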