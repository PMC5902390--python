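"""Shared fixtures and independent brute-force oracles.

The oracles recompute every geometric detection with plain O(n^2) loops
over atom records — no trees, no shared code paths with the detectors —
so agreement between a detector and its oracle is meaningful evidence.
They share only the published criteria (cutoffs and the covalent/dative
exclusion rules), which are part of the detection definition itself.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from genuvar import structure as st
from genuvar import synthetic_data as sd

BACKBONE = {"N", "CA", "C", "O", "OXT"}
METALS = {"CA", "MG", "ZN", "MN", "FE", "NA", "K", "CU"}


def _dist(a, b):
    return math.dist(tuple(a), tuple(b))


def flat_atoms(structure):
    """[(chain, seq, icode, resname, atom_name, element, xyz, het)]"""
    out = []
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                out.append((chain.id, res.seq, res.icode, res.name,
                            atom.name, atom.element.upper(), atom.xyz,
                            atom.het))
    return out


def oracle_hbonds(structure, max_distance=3.5, min_angle=90.0):
    """Brute-force donor/acceptor pairs as a set of unordered atom keys."""
    atoms = flat_atoms(structure)
    donors = [a for a in atoms if a[4] in st.DONOR_NAMES and not a[7]]
    acceptors = [a for a in atoms if a[4] in st.ACCEPTOR_NAMES and not a[7]]
    found = set()
    for d in donors:
        for acc in acceptors:
            if (d[0], d[1], d[2]) == (acc[0], acc[1], acc[2]):
                continue
            if (d[0] == acc[0] and abs(d[1] - acc[1]) == 1
                    and d[4] in BACKBONE and acc[4] in BACKBONE):
                continue
            if _dist(d[6], acc[6]) > max_distance:
                continue
            antecedent = None
            best = 2.0
            for other in atoms:
                if (other[0], other[1], other[2]) != (d[0], d[1], d[2]):
                    continue
                if other[4] == d[4]:
                    continue
                dd = _dist(other[6], d[6])
                if dd < best:
                    best, antecedent = dd, other
            if antecedent is not None:
                v1 = np.asarray(antecedent[6]) - np.asarray(d[6])
                v2 = np.asarray(acc[6]) - np.asarray(d[6])
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                if math.degrees(math.acos(max(-1, min(1, cosang)))) < min_angle:
                    continue
            found.add(frozenset(((d[0], d[1], d[2], d[4]),
                                 (acc[0], acc[1], acc[2], acc[4]))))
    return found


def oracle_disulfides(structure, cutoff=2.3):
    atoms = flat_atoms(structure)
    sgs = [a for a in atoms if a[3] == "CYS" and a[4] == "SG"]
    pairs = set()
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            if _dist(sgs[i][6], sgs[j][6]) <= cutoff:
                pairs.add(frozenset(((sgs[i][0], sgs[i][1], sgs[i][2]),
                                     (sgs[j][0], sgs[j][1], sgs[j][2]))))
    return pairs


def oracle_clashes(structure, focus=None, threshold=0.4,
                   disulfide_cutoff=2.3, metal_bond_cutoff=3.0):
    """Set of unordered clashing atom keys by exhaustive enumeration."""
    atoms = flat_atoms(structure)
    ss = oracle_disulfides(structure, disulfide_cutoff)
    found = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            rid_a, rid_b = (a[0], a[1], a[2]), (b[0], b[1], b[2])
            if rid_a == rid_b:
                continue
            if focus is not None and focus not in (rid_a[:2], rid_b[:2]):
                continue
            if (a[0] == b[0] and abs(a[1] - b[1]) == 1
                    and a[4] in BACKBONE and b[4] in BACKBONE):
                continue
            if frozenset((rid_a, rid_b)) in ss and {a[4], b[4]} <= {"SG", "CB"}:
                continue
            d = _dist(a[6], b[6])
            if d <= metal_bond_cutoff and (a[5] in METALS or b[5] in METALS):
                continue
            vdw = (st.VDW_RADII.get(a[5], 1.70)
                   + st.VDW_RADII.get(b[5], 1.70))
            if vdw - d > threshold:
                found.add(frozenset(((*rid_a, a[4]), (*rid_b, b[4]))))
    return found


def oracle_shell(structure, cutoff=3.0, elements=("O",)):
    """Ligand atom keys of the (single) metal ion, by enumeration."""
    atoms = flat_atoms(structure)
    ions = [a for a in atoms if a[7] and a[5] in METALS]
    assert len(ions) == 1
    ion = ions[0]
    shell = set()
    for a in atoms:
        if (a[0], a[1], a[2]) == (ion[0], ion[1], ion[2]):
            continue
        if a[5] in elements and _dist(a[6], ion[6]) <= cutoff:
            shell.add((a[0], a[1], a[2], a[4]))
    return shell


def hbond_keys(hbond_set):
    return {
        frozenset((
            (b.donor.chain, b.donor.resseq, b.donor.icode, b.donor.atom),
            (b.acceptor.chain, b.acceptor.resseq, b.acceptor.icode,
             b.acceptor.atom),
        ))
        for b in hbond_set
    }


def clash_keys(clash_set):
    return {
        frozenset((
            (c.atom_a.chain, c.atom_a.resseq, c.atom_a.icode, c.atom_a.atom),
            (c.atom_b.chain, c.atom_b.resseq, c.atom_b.icode, c.atom_b.atom),
        ))
        for c in clash_set
    }


# ---------------------------------------------------------------------------
# fixture structures

@pytest.fixture(scope="session")
def hbond_structure():
    return st.read_pdb(sd.make_hbond_fixture(2.8, 160.0))


@pytest.fixture(scope="session")
def far_hbond_structure():
    return st.read_pdb(sd.make_hbond_fixture(5.5, 160.0))


@pytest.fixture(scope="session")
def disulfide_structure():
    return st.read_pdb(sd.make_disulfide_fixture(2.05))


@pytest.fixture(scope="session")
def metal_structure():
    return st.read_pdb(sd.make_metal_site_fixture(4, 2.4))


@pytest.fixture(scope="session")
def pocket_structure():
    return st.read_pdb(sd.make_clash_pocket_fixture())


@pytest.fixture(scope="session")
def hairpin_structure():
    return st.read_pdb(sd.make_hairpin_fixture())


@pytest.fixture(scope="session")
def all_fixture_structures(
    hbond_structure, far_hbond_structure, disulfide_structure,
    metal_structure, pocket_structure, hairpin_structure
):
    return {
        "hbond_pair": hbond_structure,
        "hbond_pair_far": far_hbond_structure,
        "disulfide": disulfide_structure,
        "metal_site": metal_structure,
        "clash_pocket": pocket_structure,
        "hairpin": hairpin_structure,
    }


@pytest.fixture(scope="session")
def gene_model():
    return sd.make_gene_model("ITGA2B")
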