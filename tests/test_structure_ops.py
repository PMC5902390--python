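"""Structural detectors and residue substitution, checked against the
independent brute-force oracles and the fixtures' construction truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation

from genuvar import structure as st
from genuvar import synthetic_data as sd
from conftest import (
    clash_keys,
    hbond_keys,
    oracle_clashes,
    oracle_disulfides,
    oracle_hbonds,
    oracle_shell,
)


class TestHBondDetection:
    def test_salt_bridge_fires_at_2p8(self, hbond_structure):
        bonds = st.detect_hbonds(hbond_structure)
        assert len(bonds) == 1
        (bond,) = bonds
        assert (bond.donor.resname, bond.donor.atom) == ("ARG", "NH1")
        assert (bond.acceptor.resname, bond.acceptor.atom) == ("ASP", "OD1")
        assert bond.distance == pytest.approx(2.8, abs=1e-3)

    def test_no_bond_at_5p5(self, far_hbond_structure):
        assert len(st.detect_hbonds(far_hbond_structure)) == 0

    def test_angle_criterion_rejects_below_minimum(self):
        s = st.read_pdb(sd.make_hbond_fixture(2.8, 160.0))
        strict = st.HBondCriteria(min_angle=170.0)
        assert len(st.detect_hbonds(s, strict)) == 0

    def test_potential_tier_between_cutoffs(self):
        s = st.read_pdb(sd.make_hbond_fixture(3.8, 160.0))
        firm_only = st.detect_hbonds(s)
        assert len(firm_only) == 0
        two_tier = st.detect_hbonds(
            s, st.HBondCriteria(potential_max_distance=4.0)
        )
        assert [b.tier for b in two_tier] == ["potential"]

    def test_agrees_with_oracle_on_all_fixtures(self, all_fixture_structures):
        for name, s in all_fixture_structures.items():
            assert hbond_keys(st.detect_hbonds(s)) == oracle_hbonds(s), name

    def test_rigid_body_invariance(self, all_fixture_structures):
        R = Rotation.from_euler("xyz", [31, -47, 113], degrees=True).as_matrix()
        t = np.array([5.1, -3.3, 12.7])
        for name, s in all_fixture_structures.items():
            moved = s.transformed(R, t)
            assert (
                st.detect_hbonds(moved).keys() == st.detect_hbonds(s).keys()
            ), name


class TestHBondDiff:
    def test_identity_diff_is_empty(self, hbond_structure):
        before = st.detect_hbonds(hbond_structure)
        after = st.detect_hbonds(hbond_structure)
        assert st.diff_hbonds(before, after, ("A", 591)) == ([], [])

    def test_asp_to_ala_loses_engineered_bond(self, hbond_structure):
        before = st.detect_hbonds(hbond_structure)
        mutated = st.substitute_residue(hbond_structure, "A", 591, "ALA")
        lost, gained = st.diff_hbonds(
            before, st.detect_hbonds(mutated), ("A", 591)
        )
        assert gained == []
        assert [(b.donor.atom, b.acceptor.atom) for b in lost] == [
            ("NH1", "OD1")
        ]

    def test_diff_ignores_bonds_outside_focus_scope(self, hbond_structure):
        before = st.detect_hbonds(hbond_structure)
        after = st.detect_hbonds(hbond_structure)
        # a residue with no bonds and no partners sees an empty diff
        assert st.diff_hbonds(before, after, ("A", 901)) == ([], [])


class TestSubstitution:
    def test_backbone_bitwise_identical(self, pocket_structure):
        before = {
            a.name: a.xyz.copy()
            for a in pocket_structure.residue("A", 100).atoms
            if a.name in ("N", "CA", "C", "O")
        }
        mutated = st.substitute_residue(pocket_structure, "A", 100, "TRP")
        for a in mutated.residue("A", 100).atoms:
            if a.name in before:
                assert (a.xyz == before[a.name]).all()

    def test_no_atom_outside_focus_moves(self, pocket_structure):
        mutated = st.substitute_residue(pocket_structure, "A", 100, "TRP")
        before = {
            i: a.xyz.copy() for i, a in pocket_structure.atom_ids()
            if i.resseq != 100
        }
        after = {
            i: a.xyz for i, a in mutated.atom_ids() if i.resseq != 100
        }
        assert before.keys() == after.keys()
        assert all((before[k] == after[k]).all() for k in before)

    def test_trp_side_chain_complete(self, pocket_structure):
        mutated = st.substitute_residue(pocket_structure, "A", 100, "TRP")
        names = {a.name for a in mutated.residue("A", 100).atoms}
        assert names == {
            "N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
            "CE2", "CE3", "CZ2", "CZ3", "CH2",
        }

    def test_asp_to_ala_topology(self, hbond_structure):
        mutated = st.substitute_residue(hbond_structure, "A", 591, "ALA")
        assert {a.name for a in mutated.residue("A", 591).atoms} == {
            "N", "CA", "C", "O", "CB",
        }

    def test_gly_removes_side_chain(self, pocket_structure):
        mutated = st.substitute_residue(pocket_structure, "A", 100, "GLY")
        assert {a.name for a in mutated.residue("A", 100).atoms} == {
            "N", "CA", "C", "O",
        }

    def test_same_type_rebuild_keeps_backbone(self, hbond_structure):
        mutated = st.substitute_residue(hbond_structure, "A", 591, "ASP")
        res = mutated.residue("A", 591)
        orig = hbond_structure.residue("A", 591)
        for name in ("N", "CA", "C", "O"):
            assert (res.atom(name).xyz == orig.atom(name).xyz).all()
        assert {a.name for a in res.atoms} == {a.name for a in orig.atoms}

    def test_top_rotamer_chi_angles_applied(self, pocket_structure):
        from genuvar._rotamers import CHI_ATOMS, RotamerLibrary
        from genuvar.structure import _dihedral

        lib = RotamerLibrary()
        mutated = st.substitute_residue(
            pocket_structure, "A", 100, "LEU", lib
        )
        res = mutated.residue("A", 100)
        for quad, target in zip(CHI_ATOMS["LEU"], lib.top("LEU")):
            realized = _dihedral(*(res.atom(n).xyz for n in quad))
            assert realized == pytest.approx(target, abs=1.0)

    def test_missing_backbone_unmodelable(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        s = st.read_pdb(text)
        with pytest.raises(st.CannotModelError):
            st.substitute_residue(s, "A", 1, "TRP")

    def test_unknown_residue_position(self, hbond_structure):
        with pytest.raises(KeyError):
            st.substitute_residue(hbond_structure, "A", 999, "ALA")


class TestClashes:
    def test_pocket_native_clash_free(self, pocket_structure):
        assert len(st.detect_clashes(pocket_structure, ("A", 100))) == 0

    def test_bulky_substitution_clashes(self, pocket_structure):
        mutated = st.substitute_residue(pocket_structure, "A", 100, "TRP")
        assert len(st.detect_clashes(mutated, ("A", 100))) >= 1

    def test_smaller_substitution_stays_clean(self, pocket_structure):
        mutated = st.substitute_residue(pocket_structure, "A", 100, "GLY")
        assert len(st.detect_clashes(mutated, ("A", 100))) == 0

    def test_agrees_with_oracle_on_all_fixtures(self, all_fixture_structures):
        for name, s in all_fixture_structures.items():
            assert clash_keys(st.detect_clashes(s)) == oracle_clashes(s), name
        mutated = st.substitute_residue(
            all_fixture_structures["clash_pocket"], "A", 100, "TRP"
        )
        assert clash_keys(
            st.detect_clashes(mutated, ("A", 100))
        ) == oracle_clashes(mutated, focus=("A", 100))

    @settings(max_examples=25, derandomize=True)
    @given(thresholds=hst.lists(
        hst.floats(0.0, 3.0), min_size=2, max_size=5
    ))
    def test_count_monotone_nonincreasing_in_threshold(
        self, thresholds, pocket_structure
    ):
        mutated = st.substitute_residue(pocket_structure, "A", 100, "TRP")
        counts = [
            len(st.detect_clashes(mutated, ("A", 100), overlap_threshold=t))
            for t in sorted(thresholds)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_infinite_threshold_gives_empty_set(self, metal_structure):
        assert len(
            st.detect_clashes(metal_structure, overlap_threshold=float("inf"))
        ) == 0


class TestDisulfides:
    def test_bridged_pair_detected(self, disulfide_structure):
        pairs = st.detect_disulfides(disulfide_structure)
        assert [(a[1], b[1]) for a, b, _ in pairs] == [(633, 639)]

    def test_long_separation_not_bridged(self):
        s = st.read_pdb(sd.make_disulfide_fixture(4.0))
        assert st.detect_disulfides(s) == []

    @pytest.mark.parametrize("which", [633, 639])
    def test_substituting_either_cys_breaks_bridge(
        self, disulfide_structure, which
    ):
        mutated = st.substitute_residue(disulfide_structure, "A", which, "SER")
        assert st.detect_disulfides(mutated) == []

    def test_agrees_with_oracle(self, all_fixture_structures):
        for name, s in all_fixture_structures.items():
            found = {
                frozenset((a, b)) for a, b, _ in st.detect_disulfides(s)
            }
            assert found == oracle_disulfides(s), name


class TestMetalCoordination:
    def test_genu_like_shell(self, metal_structure):
        shell = st.metal_coordination(metal_structure, ("A", 801))
        assert shell.size == 4
        by_res = {
            lig.atom.resseq: lig.ligand_type for lig in shell.ligands
        }
        assert by_res == {
            633: "backbone_carbonyl",
            636: "side_chain",
            638: "backbone_carbonyl",
            673: "side_chain",
        }

    def test_out_of_range_ligands_excluded(self):
        s = st.read_pdb(sd.make_metal_site_fixture(4, 3.5))
        assert st.metal_coordination(s, ("A", 801), cutoff=3.0).size == 0

    def test_empty_site(self):
        s = st.read_pdb(sd.make_metal_site_fixture(0, 2.4))
        assert st.metal_coordination(s, ("A", 801)).size == 0

    def test_zero_cutoff_gives_empty_shell(self, metal_structure):
        assert st.metal_coordination(
            metal_structure, ("A", 801), cutoff=0.0
        ).size == 0

    def test_agrees_with_oracle(self, metal_structure):
        shell = st.metal_coordination(metal_structure, ("A", 801))
        found = {
            (l.atom.chain, l.atom.resseq, l.atom.icode, l.atom.atom)
            for l in shell.ligands
        }
        assert found == oracle_shell(metal_structure)


class TestCoordinationDisruption:
    def test_glu_to_lys_removes_side_chain_ligand(self, metal_structure):
        d = st.coordination_disruption(
            metal_structure, ("A", 801), ("A", 673, "LYS")
        )
        assert d.side_chain_ligand_removed
        assert not d.disulfide_lost

    def test_cys_to_ser_keeps_carbonyl_breaks_bridge(self, metal_structure):
        d = st.coordination_disruption(
            metal_structure, ("A", 801), ("A", 633, "SER")
        )
        assert not d.side_chain_ligand_removed
        assert d.disulfide_lost
        assert ("A", 633, "") in d.shell_after.residues

    def test_non_ligand_substitution_all_flags_false(self, metal_structure):
        # scaffold residue: no ligand atom, no disulfide, far from the ion
        d = st.coordination_disruption(
            metal_structure, ("A", 801), ("A", 901, "ALA")
        )
        assert not d.any_flag

    def test_bridge_partner_substitution_loses_disulfide_only(
        self, metal_structure
    ):
        d = st.coordination_disruption(
            metal_structure, ("A", 801), ("A", 639, "ALA")
        )
        assert d.disulfide_lost
        assert not d.side_chain_ligand_removed


class TestDistancesAndOrientation:
    def test_engineered_pair_distance(self, hbond_structure):
        assert st.min_distance(
            hbond_structure, ("A", 551), ("A", 591), ("NH1", "OD1")
        ) == pytest.approx(2.8, abs=1e-3)

    def test_residue_vs_itself_is_zero(self, hbond_structure):
        assert st.min_distance(hbond_structure, ("A", 551), ("A", 551)) == 0.0

    def test_core_facing_side_chain(self, hairpin_structure):
        core = [("A", n) for n in range(301, 307)]
        assert st.side_chain_orientation(
            hairpin_structure, ("A", 200), core
        ) == "core"

    def test_exterior_facing_side_chain(self, hairpin_structure):
        core = [("A", n) for n in range(301, 307)]
        assert st.side_chain_orientation(
            hairpin_structure, ("A", 201), core
        ) == "exterior"

    def test_gly_orientation_undefined(self, hairpin_structure):
        core = [("A", n) for n in range(301, 307)]
        assert st.side_chain_orientation(
            hairpin_structure, ("A", 301), core
        ) is None


class TestRotamerLibrary:
    def test_probabilities_sorted_descending(self):
        lib = st.RotamerLibrary()
        for states in lib.rotamers.values():
            probs = [p for _, p in states]
            assert probs == sorted(probs, reverse=True)

    def test_top_selection_rule(self):
        lib = st.RotamerLibrary()
        states = lib.rotamers["LEU"]
        assert lib.top("LEU") == states[0][0]
        assert lib.top("GLY") == ()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            st.RotamerLibrary(rotamers={"SER": [((64.0,), 1.5)]})

    def test_file_loader_roundtrip(self, tmp_path):
        path = tmp_path / "rotamers.txt"
        path.write_text("# custom\nSER 64.0 0.4\nSER -65.0 0.6\n")
        lib = st.RotamerLibrary.from_file(path)
        assert lib.top("SER") == (-65.0,)
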