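"""Fixture generators: determinism and construction-level ground truth.

Geometric claims are verified here by direct distance computation on the
emitted coordinates (the construction oracle), not via the detectors —
detector agreement lives in the structural tests.
"""

import math

import numpy as np
import pytest

from genuvar import structure as st
from genuvar import synthetic_data as sd
from genuvar.coordinates import mature_position


def _atom_xyz(structure, seq, name, chain="A"):
    return structure.residue(chain, seq).atom(name).xyz


ALL_SPECS = [
    sd.FixtureSpec.create("hbond_pair", donor_acceptor_distance=2.8, angle=160.0),
    sd.FixtureSpec.create("disulfide", sg_sg_distance=2.05),
    sd.FixtureSpec.create("metal_site", n_ligands=4, ligand_distance=2.4),
    sd.FixtureSpec.create("clash_pocket"),
    sd.FixtureSpec.create("hairpin"),
    sd.FixtureSpec.create("msa", seed=5, n_sequences=8,
                          column_conservation=(1.0, 0.5)),
]


class TestDeterminism:
    @pytest.mark.parametrize(
        "spec", ALL_SPECS, ids=lambda s: s.kind
    )
    def test_identical_spec_gives_identical_bytes(self, spec):
        assert sd.build_fixture(spec) == sd.build_fixture(spec)

    def test_msa_seed_changes_output(self):
        a = sd.make_msa(10, [0.5], seed=1)
        b = sd.make_msa(10, [0.5], seed=2)
        assert a != b

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sd.build_fixture(sd.FixtureSpec.create("nonsense"))


class TestHBondFixtureGeometry:
    @pytest.mark.parametrize("distance", [2.0, 2.8, 3.5, 5.5, 6.0])
    def test_requested_distance_realized(self, distance):
        s = st.read_pdb(sd.make_hbond_fixture(distance, 160.0))
        realized = math.dist(
            _atom_xyz(s, 551, "NH1"), _atom_xyz(s, 591, "OD1")
        )
        assert realized == pytest.approx(distance, abs=1e-3)

    @pytest.mark.parametrize("angle", [100.0, 130.0, 160.0, 180.0])
    def test_requested_angle_realized(self, angle):
        s = st.read_pdb(sd.make_hbond_fixture(2.8, angle))
        cz = _atom_xyz(s, 551, "CZ")
        nh1 = _atom_xyz(s, 551, "NH1")
        od1 = _atom_xyz(s, 591, "OD1")
        v1, v2 = cz - nh1, od1 - nh1
        realized = math.degrees(math.acos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ))
        assert realized == pytest.approx(angle, abs=0.1)

    @pytest.mark.parametrize("bad", [1.5, 6.5, 0.0, -2.8])
    def test_distance_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.make_hbond_fixture(bad, 160.0)

    def test_engineered_contact_is_the_only_close_pair(self):
        """No unintended donor/acceptor pair sneaks inside H-bond range."""
        s = st.read_pdb(sd.make_hbond_fixture(2.8, 160.0))
        atoms = [(i, a) for i, a in s.atom_ids()]
        close = []
        for di, da in atoms:
            if di.atom not in st.DONOR_NAMES:
                continue
            for ai, aa in atoms:
                if ai.atom not in st.ACCEPTOR_NAMES:
                    continue
                if di.residue_id == ai.residue_id:
                    continue
                if abs(di.resseq - ai.resseq) == 1:
                    continue
                if math.dist(tuple(da.xyz), tuple(aa.xyz)) <= 3.5:
                    close.append((di, ai))
        assert [(c[0].atom, c[1].atom) for c in close] == [("NH1", "OD1")]


class TestDisulfideFixture:
    @pytest.mark.parametrize("distance", [2.05, 4.0])
    def test_sg_separation_exact(self, distance):
        s = st.read_pdb(sd.make_disulfide_fixture(distance))
        realized = math.dist(
            _atom_xyz(s, 633, "SG"), _atom_xyz(s, 639, "SG")
        )
        assert realized == pytest.approx(distance, abs=1e-3)

    def test_roundtrip_preserves_distance(self):
        s = st.read_pdb(sd.make_disulfide_fixture(2.05))
        s2 = st.read_pdb(st.write_pdb(s))
        assert math.dist(
            _atom_xyz(s2, 633, "SG"), _atom_xyz(s2, 639, "SG")
        ) == pytest.approx(2.05, abs=1e-3)

    def test_renumbering(self):
        s = st.read_pdb(
            sd.make_disulfide_fixture(2.05, residue_numbers=(705, 718))
        )
        assert s.residue("A", 705).name == "CYS"
        assert s.residue("A", 718).name == "CYS"

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            sd.make_disulfide_fixture(0.0)


class TestMetalFixture:
    def test_four_ligands_at_requested_distance(self):
        s = st.read_pdb(sd.make_metal_site_fixture(4, 2.4))
        ion = _atom_xyz(s, 801, "CA")
        expected = {
            (633, "O"), (636, "OD1"), (638, "O"), (673, "OE1"),
        }
        for seq, name in expected:
            assert math.dist(ion, _atom_xyz(s, seq, name)) == pytest.approx(
                2.4, abs=1e-3
            )

    def test_no_unintended_oxygen_near_ion(self):
        s = st.read_pdb(sd.make_metal_site_fixture(4, 2.4))
        ion = _atom_xyz(s, 801, "CA")
        within = [
            (i.resseq, i.atom) for i, a in s.atom_ids()
            if a.element == "O" and math.dist(ion, tuple(a.xyz)) <= 3.0
        ]
        assert sorted(within) == [
            (633, "O"), (636, "OD1"), (638, "O"), (673, "OE1"),
        ]

    @pytest.mark.parametrize("n", [0, 1, 2, 3, 6])
    def test_generic_ligand_counts(self, n):
        s = st.read_pdb(sd.make_metal_site_fixture(n, 2.4))
        ion = _atom_xyz(s, 801, "CA")
        within = [
            1 for i, a in s.atom_ids()
            if a.element == "O" and math.dist(ion, tuple(a.xyz)) <= 3.0
        ]
        assert len(within) == n

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sd.make_metal_site_fixture(-1, 2.4)


class TestScaffoldSeparation:
    @pytest.mark.parametrize("kind", [
        "hbond_pair", "disulfide", "metal_site", "clash_pocket", "hairpin",
    ])
    def test_scaffold_at_least_8A_from_feature(self, kind):
        s = st.read_pdb(sd.build_fixture(sd.FixtureSpec.create(kind)))
        feature = [a.xyz for i, a in s.atom_ids() if i.resseq < 900]
        scaffold = [a.xyz for i, a in s.atom_ids() if i.resseq >= 900]
        assert scaffold, "scaffold residues missing"
        gap = min(
            math.dist(tuple(f), tuple(g)) for f in feature for g in scaffold
        )
        assert gap >= 8.0


class TestGeneModel:
    def test_cDNA_protein_correspondences(self, gene_model):
        assert gene_model.codon(591) == "GAC"
        assert gene_model.protein()[590] == "D"
        assert gene_model.codon(626) == "CAG"
        assert gene_model.protein()[625] == "Q"

    def test_cds_shape(self, gene_model):
        assert len(gene_model.cds) % 3 == 0
        assert gene_model.cds.startswith("ATG")
        assert gene_model.signal_peptide_length == 31

    def test_beta3_model(self):
        beta3 = sd.make_gene_model("ITGB3")
        assert beta3.signal_peptide_length == 26
        assert beta3.protein()[144] == "D"
        assert mature_position(beta3, 145) == 119

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            sd.make_gene_model("ITGB1")
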