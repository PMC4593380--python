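"""PDB reading, interaction detection, SASA/burial and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_interactions, quaternion_superpose_rmsd
from mxamut.structure import (
    InteractionCriteria,
    ReferenceRoute,
    classify_burial,
    detect_interactions,
    residue_environment,
    sasa,
    select_reference,
    superpose,
)
from mxamut.synthetic_data import (
    make_burial_fixture,
    make_dimer_fixture,
    make_interaction_fixture,
)

ALTLOC_PDB = """\
ATOM      1  N   ARG A 310      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ARG A 310      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  NH1AARG A 310      15.000  10.000  10.000  0.60  0.00           N
ATOM      4  NH1BARG A 310      15.000  12.000  10.000  0.40  0.00           N
HETATM    5 MG    MG A 901       0.000   0.000   0.000  1.00  0.00          MG
HETATM    6  O   HOH A 902       2.000   2.000   2.000  1.00  0.00           O
ATOM      7  H   ARG A 310      10.500  10.500  10.000  1.00  0.00           H
END
"""


class TestReadStructure:
    def test_fixture_round_trip_preserves_planted_coordinates(self, load_pdb):
        text, truth = make_interaction_fixture("salt_bridge", 3.25)
        model = load_pdb(text)
        assert len(model.residues) == 2
        nz = next(a for a in model.residue("A", 10).atoms if a.name == "NZ")
        od1 = next(a for a in model.residue("A", 20).atoms if a.name == "OD1")
        assert np.linalg.norm(nz.xyz - od1.xyz) == pytest.approx(3.25, abs=1e-3)

    def test_altloc_resolved_to_highest_occupancy(self, load_pdb):
        model = load_pdb(ALTLOC_PDB)
        res = model.residue("A", 310)
        nh1 = [a for a in res.atoms if a.name == "NH1"]
        assert len(nh1) == 1
        assert nh1[0].altloc == "A" and nh1[0].occupancy == pytest.approx(0.6)

    def test_waters_and_hydrogens_dropped_ligands_kept(self, load_pdb):
        model = load_pdb(ALTLOC_PDB)
        names = {a.name for a in model.residue("A", 310).atoms}
        assert "H" not in names
        assert [lig.name for lig in model.ligands] == ["MG"]

    def test_empty_file_is_format_error(self, load_pdb):
        with pytest.raises(ValueError):
            load_pdb("REMARK no atoms here\nEND\n")


class TestDetectInteractions:
    @pytest.mark.parametrize(
        "kind, distance, expected_kinds",
        [
            ("salt_bridge", 3.0, ["salt_bridge"]),
            ("salt_bridge", 4.0, ["salt_bridge"]),
            ("salt_bridge", 4.01, []),
            ("hbond", 2.6, []),  # below the lower window edge
            ("hbond", 3.0, ["hydrogen_bond"]),
            ("hbond", 3.6, []),
            ("hydrophobic", 3.9, ["hydrophobic"]),
            ("hydrophobic", 4.2, []),
        ],
    )
    def test_planted_pair_detection(self, load_pdb, kind, distance, expected_kinds):
        text, _ = make_interaction_fixture(kind, distance)
        model = load_pdb(text)
        found = detect_interactions(model, "A", 10)
        assert [i.kind for i in found] == expected_kinds
        for i in found:
            assert i.distance == pytest.approx(distance, abs=1e-3)

    def test_salt_bridge_window_takes_priority_over_hbond(self, load_pdb):
        # a charged pair inside the H-bond window reports one salt bridge only
        text, _ = make_interaction_fixture("salt_bridge", 3.0)
        found = detect_interactions(load_pdb(text), "A", 10)
        assert len(found) == 1 and found[0].kind == "salt_bridge"

    def test_interactions_are_symmetric(self, load_pdb):
        text, _ = make_interaction_fixture("salt_bridge", 3.1)
        model = load_pdb(text)
        from_a = {i.canonical() for i in detect_interactions(model, "A", 10)}
        from_b = {i.canonical() for i in detect_interactions(model, "A", 20)}
        assert from_a == from_b != set()

    def test_inter_chain_scope(self, load_pdb):
        text, _ = make_dimer_fixture(3.2)
        found = detect_interactions(load_pdb(text), "A", 10)
        assert [(i.kind, i.scope) for i in found] == [("salt_bridge", "inter_chain")]
        merged, _ = make_dimer_fixture(3.2, single_chain=True)
        found = detect_interactions(load_pdb(merged), "A", 10)
        assert [(i.kind, i.scope) for i in found] == [("salt_bridge", "intra_chain")]

    def test_environment_lists_planted_pocket(self, load_pdb):
        text, _ = make_interaction_fixture("hydrophobic_pocket", 3.8)
        env = residue_environment(load_pdb(text), "A", 50)
        assert len(env) == 6
        assert all(i.kind == "hydrophobic" for inters in env.values() for i in inters)

    def test_isolated_residue_has_empty_environment(self, load_pdb):
        text, _ = make_interaction_fixture("salt_bridge", 3.0)
        model = load_pdb(text)
        model.residues = [model.residues[0]]  # strip the partner
        assert residue_environment(model, "A", 10) == {}

    def test_matches_brute_force_oracle(self, load_pdb):
        rng = np.random.default_rng(42)
        kinds = ["salt_bridge", "hbond", "hydrophobic", "hydrophobic_pocket"]
        for trial in range(25):
            kind = kinds[trial % 4]
            lo = 2.9 if kind == "hydrophobic_pocket" else 2.0
            d = float(rng.uniform(lo, 4.6))
            text, _ = make_interaction_fixture(kind, round(d, 3), seed=trial)
            model = load_pdb(text, name=f"f{trial}.pdb")
            target = 50 if kind == "hydrophobic_pocket" else 10
            ours = {i.canonical() for i in detect_interactions(model, "A", target)}
            assert ours == brute_force_interactions(model, "A", target)

    def test_invariant_under_rigid_motion(self, load_pdb):
        text, _ = make_interaction_fixture("salt_bridge", 3.2)
        model = load_pdb(text)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = model.transformed(R, np.array([5.0, -3.0, 8.0]))
        base = {(i.kind, i.res_b, round(i.distance, 6)) for i in detect_interactions(model, "A", 10)}
        after = {(i.kind, i.res_b, round(i.distance, 6)) for i in detect_interactions(moved, "A", 10)}
        assert base == after

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            InteractionCriteria(hbond_min=3.6, hbond_max=3.5)
        with pytest.raises(ValueError):
            InteractionCriteria(contact_max=0)


class TestSasaAndBurial:
    def test_single_atom_closed_form(self, load_pdb):
        # one isolated N atom: area = 4*pi*(r+probe)^2 within 2% at 960 points
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "END\n"
        )
        model = load_pdb(text)
        result = sasa(model)
        expected = 4 * np.pi * (1.55 + 1.4) ** 2
        assert result["atom"][0] == pytest.approx(expected, rel=0.02)

    def test_enclosed_atom_has_zero_area(self, load_pdb):
        text, _ = make_burial_fixture(buried=True)
        model = load_pdb(text)
        result = sasa(model)
        res = model.residue("A", 50)
        assert result["residue"][res.id]["total"] == pytest.approx(0.0, abs=1e-6)

    def test_two_atom_system_matches_monte_carlo_oracle(self, load_pdb):
        text = (
            "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   3       2.500   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        model = load_pdb(text)
        ours = sasa(model)["atom"]
        # independent Monte Carlo estimate with the same radii
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        r = 1.70 + 1.4
        centers = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        for i in range(2):
            sphere = centers[i] + r * pts
            other = centers[1 - i]
            frac = np.mean(np.sum((sphere - other) ** 2, axis=1) > r**2)
            assert ours[i] == pytest.approx(4 * np.pi * r**2 * frac, rel=0.03)

    def test_sasa_invariant_under_translation(self, load_pdb):
        # translation leaves the test-point lattice geometry unchanged: exact
        text, _ = make_interaction_fixture("hydrophobic_pocket", 3.8)
        model = load_pdb(text)
        moved = model.transformed(np.eye(3), np.array([-2.0, 6.0, 1.0]))
        assert np.allclose(sasa(model)["atom"], sasa(moved)["atom"], atol=1e-6)

    def test_sasa_stable_under_rotation_to_lattice_resolution(self, load_pdb):
        # rotating the model re-samples the fixed sphere lattice, so areas
        # agree only to discretization error, which shrinks with point count
        text, _ = make_interaction_fixture("hydrophobic_pocket", 3.8)
        model = load_pdb(text)
        R = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = model.transformed(R, np.zeros(3))
        a = sasa(model, n_points=4000)["atom"]
        b = sasa(moved, n_points=4000)["atom"]
        assert np.abs(a - b).max() < 0.5  # A^2, per atom
        assert abs(a.sum() - b.sum()) / a.sum() < 0.01

    def test_burial_classification(self, load_pdb):
        buried_text, _ = make_burial_fixture(buried=True)
        assert classify_burial(load_pdb(buried_text), "A", 50).status == "buried"
        exposed_text, _ = make_burial_fixture(buried=False)
        assert classify_burial(load_pdb(exposed_text, name="e.pdb"), "A", 50).status == "exposed"

    def test_missing_residue_is_unresolved(self, load_pdb):
        text, _ = make_burial_fixture(buried=False)
        assert classify_burial(load_pdb(text), "A", 999).status == "unresolved"


class TestReferenceRouting:
    @pytest.mark.parametrize(
        "position, expected",
        [
            (95, "4P4S"),   # Switch I needs the nucleotide-bound model
            (96, "4P4S"),
            (218, "4P4U"),
            (326, "4P4U"),
            (449, "3LJB"),
            (632, "3SZR"),
            (654, "3SZR"),
            (540, "none"),  # L4 is disordered in every deposit
            (27, "none"),
        ],
    )
    def test_routing(self, position, expected):
        assert select_reference(position) == expected

    def test_route_from_config_matches_default(self):
        assert ReferenceRoute.from_config() == ReferenceRoute()


class TestSuperpose:
    def test_identical_sets_have_zero_rmsd(self):
        A = np.random.default_rng(0).normal(size=(12, 3))
        _, _, rmsd = superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_removed(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 3)) * 5
        R = Rotation.from_euler("xyz", [0.5, 1.2, -0.8]).as_matrix()
        B = A @ R.T + np.array([3.0, -7.0, 2.0])
        Rf, tf, rmsd = superpose(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(Rf) == pytest.approx(1.0, abs=1e-9)

    def test_single_displacement_bounded_and_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            n = int(rng.integers(4, 40))
            A = rng.normal(size=(n, 3)) * 4
            B = A.copy()
            d = float(rng.uniform(0.1, 2.0))
            B[0] += np.array([d, 0.0, 0.0])
            _, _, rmsd = superpose(A, B)
            assert rmsd <= d / np.sqrt(n) + 1e-9
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(A, B), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            superpose(line, line)
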