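"""Shrake-Rupley surface areas, RSA normalization and interface detection."""

import numpy as np
import pytest

from mthfrvar.structure_sasa import (
    MAX_ASA_THEORETICAL,
    SasaResult,
    Structure,
    StructureError,
    classify_exposure,
    component_sasa,
    golden_spiral_points,
    interface_residues,
    read_structure,
    relative_accessibility,
    shrake_rupley,
)
from mthfrvar.synthetic_data import make_toy_dimer, make_toy_structure


def _single_atom(radius):
    return Structure(
        chain_ids=("A",),
        res_nums=np.array([1]),
        res_names=("GLY",),
        atom_names=("CA",),
        elements=("C",),
        coords=np.zeros((1, 3)),
        het_flags=np.array([False]),
        radii=np.array([radius]),
    )


def _two_atoms(r1, r2, separation):
    return Structure(
        chain_ids=("A", "A"),
        res_nums=np.array([1, 2]),
        res_names=("GLY", "GLY"),
        atom_names=("CA", "CA"),
        elements=("C", "C"),
        coords=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
        het_flags=np.array([False, False]),
        radii=np.array([r1, r2]),
    )


def _two_sphere_oracle_quadrature(r1, r2, separation, probe, n=1_200_000, seed=7):
    """Independent Monte-Carlo quadrature of the two-expanded-sphere system."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    expanded = np.array([r1 + probe, r2 + probe])
    total = 0.0
    for i, other in ((0, 1), (1, 0)):
        points = rng.normal(size=(n, 3))
        points /= np.linalg.norm(points, axis=1, keepdims=True)
        points = centers[i] + expanded[i] * points
        free = (
            np.linalg.norm(points - centers[other], axis=1) >= expanded[other]
        ).mean()
        total += 4.0 * np.pi * expanded[i] ** 2 * free
    return total


def _two_sphere_oracle_analytic(r1, r2, separation, probe):
    """Closed-form accessible area of two intersecting expanded spheres."""
    e1, e2, d = r1 + probe, r2 + probe, separation
    if d >= e1 + e2:
        return 4.0 * np.pi * (e1**2 + e2**2)
    total = 0.0
    for a, b in ((e1, e2), (e2, e1)):
        cos_cap = (a**2 + d**2 - b**2) / (2 * a * d)
        cap = 2.0 * np.pi * a**2 * (1.0 - cos_cap)
        total += 4.0 * np.pi * a**2 - cap
    return total


class TestSingleAtom:
    def test_isolated_sphere_is_analytic_for_any_quadrature(self):
        structure = _single_atom(1.88)
        expected = 4.0 * np.pi * (1.88 + 1.4) ** 2  # ~135.19
        for n_points in (2, 100, 960, 1920):
            result = shrake_rupley(structure, probe_radius=1.4, n_points=n_points)
            assert result.total_asa == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(135.194, abs=1e-3)

    def test_shell_fully_buries_central_atom(self):
        shell, _ = make_toy_structure("shell")
        result = shrake_rupley(shell)
        assert result.per_atom_asa[0] == 0.0


class TestTwoSpheres:
    def test_matches_independent_high_resolution_oracles_within_1_percent(self):
        r1, r2, sep, probe = 1.88, 1.6, 2.5, 1.4
        ours = shrake_rupley(
            _two_atoms(r1, r2, sep), probe_radius=probe, n_points=960
        ).total_asa
        analytic = _two_sphere_oracle_analytic(r1, r2, sep, probe)
        quadrature = _two_sphere_oracle_quadrature(r1, r2, sep, probe)
        assert quadrature == pytest.approx(analytic, rel=5e-3)
        assert ours == pytest.approx(analytic, rel=0.01)

    def test_kdtree_equals_all_pairs(self):
        structure, _ = make_toy_structure("tripeptide", peptide_length=5)
        fast = shrake_rupley(structure, neighbor_search="kdtree")
        slow = shrake_rupley(structure, neighbor_search="all_pairs")
        np.testing.assert_array_equal(fast.per_atom_asa, slow.per_atom_asa)


class TestInvariances:
    def test_rigid_motion_leaves_asa_unchanged(self):
        structure, _ = make_toy_structure("tripeptide")
        base = shrake_rupley(structure).per_atom_asa
        angle = 0.9
        rotation = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0.0],
                [np.sin(angle), np.cos(angle), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        tilt = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(0.4), -np.sin(0.4)],
                [0.0, np.sin(0.4), np.cos(0.4)],
            ]
        )
        moved = structure.transformed(tilt @ rotation, np.array([12.0, -7.5, 3.25]))
        np.testing.assert_allclose(
            shrake_rupley(moved).per_atom_asa, base, atol=1e-6
        )

    def test_complex_residue_asa_never_exceeds_isolated(self):
        dimer = make_toy_dimer(5.0)
        complex_result, component_result = component_sasa(dimer, ["A"])
        complex_asa = complex_result.residue_asa()
        for key, iso in component_result.residue_asa().items():
            assert complex_asa[key] <= iso + 1e-9

    def test_doubling_points_moves_total_by_less_than_half_percent(self):
        for structure in (
            make_toy_structure("tripeptide", peptide_length=8)[0],
            make_toy_dimer(5.0),
        ):
            total_960 = shrake_rupley(structure, n_points=960).total_asa
            total_1920 = shrake_rupley(structure, n_points=1920).total_asa
            assert abs(total_1920 - total_960) / total_960 < 0.005

    def test_golden_spiral_points_unit_norm(self):
        points = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(points, axis=1), 1.0, atol=1e-12)
        assert len(np.unique(points.round(9), axis=0)) == 960


class TestRelativeAccessibility:
    def test_max_value_and_zero_map_to_100_and_0(self):
        structure = _single_atom(1.88)
        sasa = shrake_rupley(structure)
        # force ASA to the table maximum, then to zero
        table = {"GLY": sasa.total_asa}
        assert relative_accessibility(sasa, table).residues.rsa.iloc[0] == 100
        buried = SasaResult(
            per_atom_asa=np.array([0.0]),
            residues=sasa.residues.assign(asa=0.0),
            probe_radius=1.4,
            n_points=960,
        )
        assert relative_accessibility(buried).residues.rsa.iloc[0] == 0

    def test_values_above_max_clamp_to_100(self):
        structure = _single_atom(1.88)
        sasa = shrake_rupley(structure)
        table = {"GLY": sasa.total_asa / 2}
        assert relative_accessibility(sasa, table).residues.rsa.iloc[0] == 100

    def test_unknown_residue_type_names_the_residue(self):
        structure = _single_atom(1.88)
        sasa = shrake_rupley(structure)
        with pytest.raises(ValueError, match="GLY"):
            relative_accessibility(sasa, {"ALA": 129.0})

    def test_bundled_max_table_covers_standard_residues(self):
        assert len(MAX_ASA_THEORETICAL) == 20


class TestClassifyExposure:
    @pytest.mark.parametrize(
        "rsa, expected",
        [(0, "buried"), (19, "buried"), (20, "exposed"), (29, "exposed"), (100, "exposed")],
    )
    def test_threshold_is_inclusive(self, rsa, expected):
        assert classify_exposure(rsa, 20) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_exposure(120)


def _brute_force_interface(complex_structure, groups, delta, n_points=960):
    """All-pairs ddASA oracle, no neighbor pruning."""
    from mthfrvar.structure_sasa import canonical_frame, _sasa_atoms, _residue_frame

    frame = canonical_frame(complex_structure.coords)
    asa_complex = _sasa_atoms(complex_structure, 1.4, n_points, "all_pairs", frame)
    complex_map = {
        (r.chain, int(r.resnum)): float(r.asa)
        for r in _residue_frame(complex_structure, asa_complex).itertuples()
    }
    found = set()
    for group in groups:
        component = complex_structure.select_chains(group)
        asa_iso = _sasa_atoms(component, 1.4, n_points, "all_pairs", frame)
        for row in _residue_frame(component, asa_iso).itertuples():
            key = (row.chain, int(row.resnum))
            if float(row.asa) - complex_map[key] >= delta:
                found.add(key)
    return found


class TestInterface:
    def test_distant_chains_share_no_interface(self):
        dimer = make_toy_dimer(50.0)
        assert interface_residues(dimer, (("A",), ("B",))) == set()

    def test_contact_dimer_matches_brute_force_oracle(self):
        dimer = make_toy_dimer(5.0)
        ours = interface_residues(dimer, (("A",), ("B",)))
        oracle = _brute_force_interface(dimer, (("A",), ("B",)), 1.0)
        assert ours == oracle
        assert ours == {("A", 1), ("A", 2), ("A", 3), ("B", 1), ("B", 2), ("B", 3)}

    def test_symmetric_dimer_interface_mirrors_between_chains(self):
        dimer = make_toy_dimer(5.5)
        found = interface_residues(dimer, (("A",), ("B",)))
        chain_a = {r for c, r in found if c == "A"}
        chain_b = {r for c, r in found if c == "B"}
        assert chain_a == chain_b

    def test_overlapping_chain_groups_rejected(self):
        dimer = make_toy_dimer(5.0)
        with pytest.raises(ValueError, match="overlap"):
            interface_residues(dimer, (("A", "B"), ("B",)))

    def test_missing_chain_rejected(self):
        dimer = make_toy_dimer(5.0)
        with pytest.raises(StructureError, match="absent"):
            interface_residues(dimer, (("A",), ("C",)))


class TestReadStructure:
    def test_toy_pdb_round_trip(self, tmp_path):
        structure, pdb_text = make_toy_structure("single_residue")
        path = tmp_path / "toy.pdb"
        path.write_text(pdb_text)
        reread = read_structure(path)
        assert reread.n_atoms == 5
        assert len(reread.residue_keys()) == 1
        np.testing.assert_allclose(reread.coords, structure.coords, atol=1e-3)

    def test_water_only_file_is_empty_selection(self, tmp_path):
        lines = [
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O",
            "END",
        ]
        path = tmp_path / "water.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="empty selection"):
            read_structure(path)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.60  0.00           C",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        structure = read_structure(path)
        assert structure.n_atoms == 1
        assert structure.coords[0, 0] == pytest.approx(5.0)

    def test_unknown_element_without_radius_is_an_error(self, tmp_path):
        lines = [
            "ATOM      1  P   GLY A   1       0.000   0.000   0.000  1.00  0.00           P",
            "END",
        ]
        path = tmp_path / "phos.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="radius"):
            read_structure(path)
        # but an extended radii table makes it readable
        structure = read_structure(path, radii={"P": 1.9})
        assert structure.radii[0] == pytest.approx(1.9)

    def test_chain_filter_and_empty_selection(self, tmp_path):
        dimer = make_toy_dimer(5.0)
        from mthfrvar.synthetic_data import structure_to_pdb

        path = tmp_path / "dimer.pdb"
        path.write_text(structure_to_pdb(dimer))
        only_a = read_structure(path, chains=["A"])
        assert set(only_a.chain_ids) == {"A"}
        with pytest.raises(StructureError):
            read_structure(path, chains=["Z"])


class TestAgainstBiopython:
    def test_totals_agree_with_independent_implementation(self, tmp_path):
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley as BioShrakeRupley

        structure, pdb_text = make_toy_structure("tripeptide", peptide_length=4)
        path = tmp_path / "pep.pdb"
        path.write_text(pdb_text)
        bio_structure = PDBParser(QUIET=True).get_structure("pep", str(path))
        BioShrakeRupley(
            probe_radius=1.4,
            n_points=960,
            radii_dict={"C": 1.76, "N": 1.65, "O": 1.40, "S": 1.85},
        ).compute(bio_structure, level="S")
        bio_total = sum(atom.sasa for atom in bio_structure.get_atoms())
        ours = shrake_rupley(structure).total_asa
        assert ours == pytest.approx(bio_total, rel=0.01)
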