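"""Structural analysis of residue substitutions on rigid crystal backbones.

This is the structural core of the package: parse a PDB coordinate file,
replace one residue's side chain with the maximum-probability rotamer of
a new amino-acid type (the backbone never moves), and inventory the
geometric interactions — hydrogen bonds, van der Waals clashes,
disulfide bridges, metal coordination shells, side-chain orientation —
before and after the substitution.  Differencing the inventories around
the mutated site reproduces the kind of statement made about
disease-causing integrin variants: e.g. Asp->Ala in a thigh-domain loop
removes the structuring H-bonds the aspartate made with its neighbours,
while Glu->Lys at a genu Ca2+ ligand removes a side-chain carboxylate
from the coordination shell.

Crystal structures lack hydrogens, so all criteria are heavy-atom based:
an H-bond is a donor/acceptor heavy-atom pair within a distance cutoff
with a permissive angle check at the donor; clashes are van der Waals
overlaps beyond a tolerance.  All cutoffs live in small config
dataclasses and can be overridden per call.
"""

from __future__ import annotations

import copy
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._rotamers import CHI_ATOMS, RotamerLibrary
from .coordinates import three_letter

__all__ = [
    "Atom", "Residue", "Chain", "Structure", "AtomId",
    "read_pdb", "write_pdb",
    "HBond", "HBondSet", "HBondCriteria", "detect_hbonds", "diff_hbonds",
    "Clash", "ClashSet", "detect_clashes", "VDW_RADII",
    "detect_disulfides", "CoordinationShell", "metal_coordination",
    "find_metal_ions", "coordination_disruption", "CoordinationDisruption",
    "substitute_residue", "min_distance", "side_chain_orientation",
    "RotamerLibrary",
    "PDBFormatError", "EmptyStructureError", "CannotModelError",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: van der Waals radii (Angstrom) by element; standard Bondi-type values,
#: Ca2+ uses its ionic-contact radius.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "CA": 2.31, "MG": 1.73, "ZN": 1.39, "MN": 1.61, "FE": 1.56,
    "NA": 2.27, "K": 2.75, "CU": 1.40,
}
_DEFAULT_RADIUS = 1.70

METAL_ELEMENTS = frozenset({"CA", "MG", "ZN", "MN", "FE", "NA", "K", "CU"})


class PDBFormatError(ValueError):
    """A coordinate record could not be parsed."""


class EmptyStructureError(ValueError):
    """The input contained no ATOM/HETATM records."""


class CannotModelError(ValueError):
    """A substitution cannot be modelled (e.g. missing backbone atoms)."""


# ---------------------------------------------------------------------------
# data model

class AtomId(NamedTuple):
    """Fully qualified atom identifier."""

    chain: str
    resseq: int
    icode: str
    resname: str
    atom: str

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    def __str__(self) -> str:  # e.g. A/ASP591/OD1
        return f"{self.chain}/{self.resname}{self.resseq}{self.icode}/{self.atom}"


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    het: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: bad coordinates {self.xyz}")


@dataclass
class Residue:
    name: str
    seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.name}{self.seq}"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def side_chain(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    @property
    def id(self) -> tuple[int, str]:
        return (self.seq, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq == seq and r.icode == icode:
                return r
        return None


@dataclass
class Structure:
    """Chains -> residues -> atoms with coordinates in Angstrom."""

    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def residue(self, chain_id: str, seq: int, icode: str = "") -> Residue | None:
        c = self.chain(chain_id)
        return c.residue(seq, icode) if c else None

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def atom_ids(self) -> list[tuple[AtomId, Atom]]:
        return [
            (AtomId(c.id, r.seq, r.icode, r.name, a.name), a)
            for c, r, a in self.iter_atoms()
        ]

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, _, a in out.iter_atoms():
            a.xyz = R @ a.xyz + t
        return out


# ---------------------------------------------------------------------------
# PDB I/O

def _validate_coordinate_lines(text: str) -> int:
    n_coord = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n_coord += 1
        if len(line) < 54:
            raise PDBFormatError(
                f"line {lineno}: truncated {rec} record ({len(line)} chars)"
            )
        try:
            int(line[22:26])
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError as exc:
            raise PDBFormatError(
                f"line {lineno}: malformed {rec} record: {exc}"
            ) from exc
    return n_coord


def read_pdb(text: str, *, keep_waters: bool = False) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Metal ions and other HETATM groups are retained; waters are dropped
    unless ``keep_waters``.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken in favour of conformer 'A').
    Malformed coordinate records raise :class:`PDBFormatError` naming the
    line; input without any coordinate record raises
    :class:`EmptyStructureError`.
    """
    if _validate_coordinate_lines(text) == 0:
        raise EmptyStructureError("no ATOM/HETATM records in input")
    st = gemmi.read_pdb_string(text)
    model = st[0]
    structure = Structure()
    for gchain in model:
        chain = Chain(id=gchain.name.strip() or "A")
        for gres in gchain:
            if not keep_waters and gres.name.strip() in WATER_NAMES:
                continue
            # resolve altlocs: highest occupancy, tie -> conformer 'A'
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                cur = best.get(ga.name)
                if cur is None or _altloc_rank(ga) > _altloc_rank(cur):
                    best[ga.name] = ga
            residue = Residue(
                name=gres.name.strip(),
                seq=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
            )
            het = gres.het_flag == "H"
            for ga in best.values():
                residue.atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name.upper(),
                        xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        het=het,
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            structure.chains.append(chain)
    if structure.n_atoms == 0:
        raise EmptyStructureError("no atoms retained after filtering")
    return structure


def _altloc_rank(atom: gemmi.Atom) -> tuple[float, int]:
    alt = atom.altloc
    return (atom.occ, 1 if alt in ("\0", "", "A") else 0)


def write_pdb(structure: Structure) -> str:
    """Serialise to minimal PDB text (ATOM/HETATM/TER/END, occupancy
    1.00, B-factor 0.00, element in columns 77-78)."""
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                rec = "HETATM" if atom.het else "ATOM  "
                name = atom.name
                if len(name) < 4 and len(atom.element) < 2:
                    name = f" {name:<3s}"
                else:
                    name = f"{name:<4s}"
                x, y, z = atom.xyz
                lines.append(
                    f"{rec}{serial:5d} {name} {res.name:>3s} {chain.id:1s}"
                    f"{res.seq:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# geometry helpers

def _distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping point set P onto Q."""
    Pm, Qm = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pm).T @ (Q - Qm)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, Qm - R @ Pm


# ---------------------------------------------------------------------------
# hydrogen bonds

#: Heavy-atom donor/acceptor name sets (X-ray structures carry no H).
DONOR_NAMES = frozenset({
    "N", "NE", "NH1", "NH2", "ND1", "ND2", "NE1", "NE2", "NZ",
    "OG", "OG1", "OH", "SG",
})
ACCEPTOR_NAMES = frozenset({
    "O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
    "ND1", "NE2", "SD",
})


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criteria.

    ``max_distance`` bounds the firm donor-acceptor heavy-atom distance;
    pairs between ``max_distance`` and ``potential_max_distance`` are
    reported with tier ``"potential"`` (longer, tentative contacts of the
    kind drawn as 'potential H-bonds' in structure figures).  The angle
    at the donor (antecedent-donor-acceptor) must exceed ``min_angle``
    where an antecedent heavy atom exists.
    """

    max_distance: float = 3.5
    min_angle: float = 90.0
    potential_max_distance: float | None = None
    donor_names: frozenset[str] = DONOR_NAMES
    acceptor_names: frozenset[str] = ACCEPTOR_NAMES


class HBond(NamedTuple):
    donor: AtomId
    acceptor: AtomId
    distance: float
    angle: float | None
    tier: str = "firm"

    @property
    def key(self):
        """Identity of the bonded atom pair, insensitive to residue
        renaming (so a substitution does not spuriously 'change' backbone
        bonds) and to donor/acceptor ordering."""
        a = (self.donor.chain, self.donor.resseq, self.donor.icode, self.donor.atom)
        b = (self.acceptor.chain, self.acceptor.resseq, self.acceptor.icode,
             self.acceptor.atom)
        return tuple(sorted((a, b)))


@dataclass
class HBondSet:
    """Inventory of detected hydrogen bonds."""

    bonds: list[HBond] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bonds)

    def __iter__(self) -> Iterator[HBond]:
        return iter(self.bonds)

    def keys(self) -> set:
        return {b.key for b in self.bonds}

    def firm(self) -> "HBondSet":
        return HBondSet([b for b in self.bonds if b.tier == "firm"])

    def touching(self, residue_ids: Iterable[tuple[str, int, str]]) -> "HBondSet":
        rid = set(residue_ids)
        return HBondSet([
            b for b in self.bonds
            if b.donor.residue_id in rid or b.acceptor.residue_id in rid
        ])

    def partners_of(self, residue_id: tuple[str, int, str]) -> set:
        out = set()
        for b in self.bonds:
            if b.donor.residue_id == residue_id:
                out.add(b.acceptor.residue_id)
            elif b.acceptor.residue_id == residue_id:
                out.add(b.donor.residue_id)
        return out


def _adjacent_backbone(a: AtomId, b: AtomId) -> bool:
    # peptide-bonded neighbours: their backbone atoms are covalently
    # connected (1-2/1-3), not hydrogen bonded / clashing
    return (
        a.chain == b.chain
        and abs(a.resseq - b.resseq) == 1
        and a.atom in BACKBONE_ATOMS
        and b.atom in BACKBONE_ATOMS
    )


def detect_hbonds(
    structure: Structure, criteria: HBondCriteria | None = None
) -> HBondSet:
    """Detect hydrogen bonds between donor and acceptor heavy atoms.

    Intra-residue pairs and covalently linked backbone atoms of adjacent
    residues are excluded.  Each unordered atom pair is reported once.
    """
    crit = criteria or HBondCriteria()
    reach = crit.potential_max_distance or crit.max_distance
    ids_atoms = structure.atom_ids()
    donors = [(i, a) for i, a in ids_atoms
              if i.atom in crit.donor_names and not a.het]
    acceptors = [(i, a) for i, a in ids_atoms
                 if i.atom in crit.acceptor_names and not a.het]
    if not donors or not acceptors:
        return HBondSet()
    tree = cKDTree(np.array([a.xyz for _, a in acceptors]))
    residues = {
        (c.id, r.seq, r.icode): r
        for c in structure.chains for r in c.residues
    }
    bonds: dict[tuple, HBond] = {}
    for did, datom in donors:
        for j in tree.query_ball_point(datom.xyz, reach):
            aid, aatom = acceptors[j]
            if did.residue_id == aid.residue_id:
                continue
            if _adjacent_backbone(did, aid):
                continue
            dist = _distance(datom.xyz, aatom.xyz)
            if dist > reach:
                continue
            angle = None
            antecedent = _nearest_bonded(residues[did.residue_id], datom)
            if antecedent is not None:
                angle = _angle(antecedent.xyz, datom.xyz, aatom.xyz)
                if angle < crit.min_angle:
                    continue
            tier = "firm" if dist <= crit.max_distance else "potential"
            bond = HBond(did, aid, dist, angle, tier)
            prev = bonds.get(bond.key)
            if prev is None or dist < prev.distance:
                bonds[bond.key] = bond
    return HBondSet(sorted(bonds.values(), key=lambda b: b.key))


def _nearest_bonded(residue: Residue, atom: Atom, cutoff: float = 2.0) -> Atom | None:
    best, best_d = None, cutoff
    for other in residue.atoms:
        if other is atom:
            continue
        d = _distance(atom.xyz, other.xyz)
        if d < best_d:
            best, best_d = other, d
    return best


def diff_hbonds(
    before: HBondSet,
    after: HBondSet,
    focus_residue: tuple[str, int] | tuple[str, int, str],
) -> tuple[list[HBond], list[HBond]]:
    """H-bonds lost and gained around a substituted residue.

    Restricted to bonds touching the focus residue or any of its
    pre-substitution partners, so unrelated parts of the structure never
    contribute.  Returns ``(lost, gained)``.
    """
    rid = focus_residue if len(focus_residue) == 3 else (*focus_residue, "")
    scope = {rid} | before.partners_of(rid)
    rel_before = before.touching(scope)
    rel_after = after.touching(scope)
    lost = [b for b in rel_before if b.key not in rel_after.keys()]
    gained = [b for b in rel_after if b.key not in rel_before.keys()]
    return lost, gained


# ---------------------------------------------------------------------------
# clashes

class Clash(NamedTuple):
    atom_a: AtomId
    atom_b: AtomId
    distance: float
    overlap: float


@dataclass
class ClashSet:
    clashes: list[Clash] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clashes)

    def __iter__(self) -> Iterator[Clash]:
        return iter(self.clashes)


def _vdw(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)


def _disulfide_sg_pairs(structure: Structure, cutoff: float) -> set:
    pairs = set()
    for (r1, r2, _d) in detect_disulfides(structure, cutoff=cutoff):
        pairs.add(frozenset((r1, r2)))
    return pairs


def detect_clashes(
    structure: Structure,
    focus_residue: tuple[str, int] | tuple[str, int, str] | None = None,
    overlap_threshold: float = 0.4,
    *,
    radii: dict[str, float] | None = None,
    disulfide_cutoff: float = 2.3,
    metal_bond_cutoff: float = 3.0,
) -> ClashSet:
    """Van der Waals overlaps between non-bonded atoms.

    A pair clashes when ``distance < vdW(a) + vdW(b) - overlap_threshold``.
    Pairs within a residue, covalently linked backbone atoms of adjacent
    residues, atoms bonded through a disulfide bridge (SG-SG plus the
    1-3 SG-CB pairs), and metal-ligand pairs within ``metal_bond_cutoff``
    (dative coordination bonds, not steric contacts) are excluded.  With
    ``focus_residue`` given, only pairs touching that residue are
    reported.
    """
    rad = radii or VDW_RADII
    ids_atoms = structure.atom_ids()
    elements = {a.element.upper() for _, a in ids_atoms}
    max_r = max(
        (rad.get(e, _DEFAULT_RADIUS) for e in elements),
        default=_DEFAULT_RADIUS,
    )
    reach = 2 * max_r
    focus_rid = None
    if focus_residue is not None:
        focus_rid = (focus_residue if len(focus_residue) == 3
                     else (*focus_residue, ""))
    ss_pairs = _disulfide_sg_pairs(structure, disulfide_cutoff)
    coords = np.array([a.xyz for _, a in ids_atoms])
    tree = cKDTree(coords)
    clashes = []
    for i, j in tree.query_pairs(reach):
        ida, atoma = ids_atoms[i]
        idb, atomb = ids_atoms[j]
        if ida.residue_id == idb.residue_id:
            continue
        if focus_rid is not None and focus_rid not in (
            ida.residue_id, idb.residue_id
        ):
            continue
        if _adjacent_backbone(ida, idb):
            continue
        if frozenset((ida.residue_id, idb.residue_id)) in ss_pairs and (
            {ida.atom, idb.atom} <= {"SG", "CB"}
        ):
            continue  # disulfide-bonded: 1-2 (SG-SG) and 1-3 (SG-CB)
        d = _distance(atoma.xyz, atomb.xyz)
        if d <= metal_bond_cutoff and (
            atoma.element.upper() in METAL_ELEMENTS
            or atomb.element.upper() in METAL_ELEMENTS
        ):
            continue  # dative metal-ligand coordination, not a clash
        overlap = (
            rad.get(atoma.element.upper(), _DEFAULT_RADIUS)
            + rad.get(atomb.element.upper(), _DEFAULT_RADIUS)
            - d
        )
        if overlap > overlap_threshold:
            clashes.append(Clash(ida, idb, d, overlap))
    clashes.sort(key=lambda c: (c.atom_a, c.atom_b))
    return ClashSet(clashes)


# ---------------------------------------------------------------------------
# disulfides and metal coordination

def detect_disulfides(
    structure: Structure, cutoff: float = 2.3
) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Cys pairs whose SG atoms lie within ``cutoff`` (default 2.3 A)."""
    sgs = []
    for c in structure.chains:
        for r in c.residues:
            if r.name == "CYS":
                sg = r.atom("SG")
                if sg is not None:
                    sgs.append(((c.id, r.seq, r.icode), sg))
    out = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = _distance(sgs[i][1].xyz, sgs[j][1].xyz)
            if d <= cutoff:
                out.append((sgs[i][0], sgs[j][0], d))
    return out


class Ligand(NamedTuple):
    atom: AtomId
    distance: float
    ligand_type: str  # "backbone_carbonyl" | "side_chain"


@dataclass
class CoordinationShell:
    """Ligand inventory of one metal ion."""

    ion: AtomId
    cutoff: float
    ligands: list[Ligand] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.ligands)

    @property
    def residues(self) -> set:
        return {lig.atom.residue_id for lig in self.ligands}

    def by_residue(self, residue_id) -> list[Ligand]:
        return [l for l in self.ligands if l.atom.residue_id == residue_id]


def find_metal_ions(structure: Structure) -> list[AtomId]:
    """HETATM atoms whose element is a common structural metal."""
    return [
        i for i, a in structure.atom_ids()
        if a.het and a.element.upper() in METAL_ELEMENTS
    ]


def metal_coordination(
    structure: Structure,
    ion: AtomId | tuple[str, int] | tuple[str, int, str],
    cutoff: float = 3.0,
    *,
    ligand_elements: Sequence[str] = ("O",),
) -> CoordinationShell:
    """Coordination shell of a metal ion.

    Ligands are atoms of the given elements (default oxygen, the
    physiological Ca2+ ligand) within ``cutoff`` of the ion, classified
    as backbone carbonyl (atom name ``O``/``OXT``) or side chain.
    ``ion`` may be an :class:`AtomId` or a ``(chain, resseq)`` residue
    reference containing a single metal atom.
    """
    ion_id, ion_atom = _resolve_ion(structure, ion)
    elements = {e.upper() for e in ligand_elements}
    ligands = []
    for aid, atom in structure.atom_ids():
        if aid.residue_id == ion_id.residue_id:
            continue
        if atom.element.upper() not in elements:
            continue
        d = _distance(ion_atom.xyz, atom.xyz)
        if d <= cutoff:
            ltype = ("backbone_carbonyl" if aid.atom in ("O", "OXT")
                     else "side_chain")
            ligands.append(Ligand(aid, d, ltype))
    ligands.sort(key=lambda l: l.distance)
    return CoordinationShell(ion=ion_id, cutoff=cutoff, ligands=ligands)


def _resolve_ion(structure: Structure, ion) -> tuple[AtomId, Atom]:
    if isinstance(ion, AtomId):
        for aid, atom in structure.atom_ids():
            if aid == ion:
                return aid, atom
        raise KeyError(f"ion {ion} not found")
    chain_id, seq, *rest = ion
    icode = rest[0] if rest else ""
    res = structure.residue(chain_id, seq, icode)
    if res is None:
        raise KeyError(f"no residue {chain_id}/{seq}{icode}")
    metals = [a for a in res.atoms if a.element.upper() in METAL_ELEMENTS]
    if len(metals) != 1:
        raise KeyError(
            f"residue {chain_id}/{seq}{icode} holds {len(metals)} metal atoms"
        )
    a = metals[0]
    return AtomId(chain_id, seq, icode, res.name, a.name), a


@dataclass
class CoordinationDisruption:
    """Effect of one substitution on a metal site."""

    substitution: tuple[str, int, str]  # chain, resseq, new_aa (3-letter)
    side_chain_ligand_removed: bool
    disulfide_lost: bool
    ion_clash: bool
    shell_before: CoordinationShell
    shell_after: CoordinationShell

    @property
    def any_flag(self) -> bool:
        return (self.side_chain_ligand_removed or self.disulfide_lost
                or self.ion_clash)


def coordination_disruption(
    structure: Structure,
    ion,
    substitution: tuple[str, int, str],
    *,
    cutoff: float = 3.0,
    disulfide_cutoff: float = 2.3,
    overlap_threshold: float = 0.4,
    library: RotamerLibrary | None = None,
) -> CoordinationDisruption:
    """Assess whether substituting one residue disrupts a metal site.

    Flags raised: the residue's side-chain ligand atom disappears from
    the shell (e.g. Glu->Lys removes a carboxylate oxygen); a disulfide
    bridge involving the residue is lost (e.g. Cys->Ser); the new side
    chain clashes with the ion itself (steric displacement of the metal).
    A substitution at a backbone-carbonyl ligand leaves the backbone
    contribution intact and raises no ligand flag.
    """
    chain_id, seq, new_aa = substitution
    rid = (chain_id, seq, "")
    before = metal_coordination(structure, ion, cutoff)
    ss_before = {
        frozenset((a, b)) for a, b, _ in
        detect_disulfides(structure, cutoff=disulfide_cutoff)
    }
    after_structure = substitute_residue(
        structure, chain_id, seq, new_aa, library=library
    )
    after = metal_coordination(after_structure, ion, cutoff)
    ss_after = {
        frozenset((a, b)) for a, b, _ in
        detect_disulfides(after_structure, cutoff=disulfide_cutoff)
    }
    had_side = any(
        l.ligand_type == "side_chain" for l in before.by_residue(rid)
    )
    has_side = any(
        l.ligand_type == "side_chain" for l in after.by_residue(rid)
    )
    lost_ss = any(rid in pair for pair in ss_before - ss_after)
    ion_id, _ = _resolve_ion(structure, ion)
    clashes = detect_clashes(
        after_structure, focus_residue=(chain_id, seq),
        overlap_threshold=overlap_threshold,
        disulfide_cutoff=disulfide_cutoff,
    )
    ion_clash = any(
        ion_id in (c.atom_a, c.atom_b) for c in clashes
    )
    return CoordinationDisruption(
        substitution=(chain_id, seq, three_letter(new_aa).upper()
                      if len(new_aa) != 3 else new_aa.upper()),
        side_chain_ligand_removed=had_side and not has_side,
        disulfide_lost=lost_ss,
        ion_clash=ion_clash,
        shell_before=before,
        shell_after=after,
    )


# ---------------------------------------------------------------------------
# residue substitution

def _ideal_template(resname: str):
    """Heavy-atom template (names, elements, coords, bonds) for a residue
    type, from the chemical component dictionary shipped with biotite."""
    import biotite.structure.info as bsinfo

    arr = bsinfo.residue(resname)
    if arr is None:
        raise CannotModelError(f"no template for residue {resname!r}")
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx = np.where(keep)[0]
    names = list(arr.atom_name[idx])
    elements = list(arr.element[idx])
    coords = arr.coord[idx].astype(float)
    remap = {old: new for new, old in enumerate(idx)}
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(idx))}
    for i, j, _order in arr.bonds.as_array():
        if i in remap and j in remap:
            adjacency[remap[i]].add(remap[j])
            adjacency[remap[j]].add(remap[i])
    return names, elements, coords, adjacency


def _downstream(adjacency: dict[int, set[int]], start: int, blocked: int) -> set[int]:
    """Indices reachable from ``start`` without passing ``blocked``."""
    seen = {start, blocked}
    out = set()
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nb in adjacency[node]:
            if nb not in seen:
                seen.add(nb)
                out.add(nb)
                queue.append(nb)
    return out


def _set_chi(
    names: list[str],
    coords: np.ndarray,
    adjacency: dict[int, set[int]],
    quad: tuple[str, str, str, str],
    target_deg: float,
) -> None:
    try:
        ia, ib, ic, id_ = (names.index(n) for n in quad)
    except ValueError:
        return  # chi atoms absent (should not happen for CCD templates)
    current = _dihedral(coords[ia], coords[ib], coords[ic], coords[id_])
    # rotating the distal atoms by +delta about the b->c axis decreases
    # the measured dihedral by delta, hence the sign flip
    delta = -np.radians(target_deg - current)
    axis = coords[ic] - coords[ib]
    axis = axis / np.linalg.norm(axis)
    origin = coords[ic]
    rot = _rodrigues(axis, delta)
    moving = _downstream(adjacency, ic, ib)
    for k in moving:
        coords[k] = origin + rot @ (coords[k] - origin)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def substitute_residue(
    structure: Structure,
    chain_id: str,
    position: int,
    new_aa: str,
    library: RotamerLibrary | None = None,
    *,
    icode: str = "",
) -> Structure:
    """Replace one residue's side chain with an ideal side chain of a new
    amino-acid type in its maximum-probability rotamer.

    The backbone (N, CA, C, O and OXT if present) keeps bit-identical
    coordinates; the side chain is rebuilt from the chemical-component
    template superimposed on the local backbone frame, then rotated to
    the library's top chi angles.  Gly removes the side chain entirely.
    Returns a new structure; the input is never mutated.
    """
    resname = three_letter(new_aa).upper() if len(new_aa) != 3 else new_aa.upper()
    lib = library or RotamerLibrary()
    out = structure.copy()
    chain = out.chain(chain_id)
    if chain is None:
        raise KeyError(f"no chain {chain_id!r}")
    res = chain.residue(position, icode)
    if res is None:
        raise KeyError(f"no residue {position}{icode} in chain {chain_id}")
    missing = [n for n in ("N", "CA", "C") if res.atom(n) is None]
    if missing:
        raise CannotModelError(
            f"cannot model {chain_id}/{res.name}{position}: missing backbone "
            f"atoms {missing}"
        )
    backbone = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    if resname == "GLY":
        res.name = resname
        res.atoms = backbone
        return out
    names, elements, coords, adjacency = _ideal_template(resname)
    for chi_quad, chi_target in zip(
        CHI_ATOMS.get(resname, []), lib.top(resname)
    ):
        _set_chi(names, coords, adjacency, chi_quad, chi_target)
    tmpl_idx = {n: i for i, n in enumerate(names)}
    P = np.array([coords[tmpl_idx[n]] for n in ("N", "CA", "C")])
    Q = np.array([res.atom(n).xyz for n in ("N", "CA", "C")])
    R, t = _kabsch(P, Q)
    coords = coords @ R.T + t
    side = [
        Atom(name=str(n), element=str(elements[i]).upper(), xyz=coords[i])
        for i, n in enumerate(names)
        if n not in BACKBONE_ATOMS
    ]
    res.name = resname
    res.atoms = backbone + side
    return out


# ---------------------------------------------------------------------------
# distances and orientation

def min_distance(
    structure: Structure,
    residue_a: tuple[str, int] | tuple[str, int, str],
    residue_b: tuple[str, int] | tuple[str, int, str],
    atom_filter: Callable[[AtomId], bool] | Iterable[str] | None = None,
) -> float:
    """Minimum interatomic distance between two residues (0 for the same
    residue).  ``atom_filter`` restricts which atoms participate, either
    a predicate on :class:`AtomId` or a set of atom names."""
    rid_a = residue_a if len(residue_a) == 3 else (*residue_a, "")
    rid_b = residue_b if len(residue_b) == 3 else (*residue_b, "")
    if rid_a == rid_b:
        return 0.0
    if atom_filter is None:
        pred = lambda aid: True
    elif callable(atom_filter):
        pred = atom_filter
    else:
        allowed = set(atom_filter)
        pred = lambda aid: aid.atom in allowed
    xs, ys = [], []
    for aid, atom in structure.atom_ids():
        if not pred(aid):
            continue
        if aid.residue_id == rid_a:
            xs.append(atom.xyz)
        elif aid.residue_id == rid_b:
            ys.append(atom.xyz)
    if not xs or not ys:
        raise KeyError(
            f"no atoms selected for {rid_a} and/or {rid_b}"
        )
    X, Y = np.array(xs), np.array(ys)
    return float(np.sqrt(((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1)).min())


def side_chain_orientation(
    structure: Structure,
    residue: tuple[str, int] | tuple[str, int, str],
    core_residues: Sequence[tuple[str, int] | tuple[str, int, str]],
) -> str | None:
    """Classify whether a side chain points into a designated core.

    The vector from CB to the centroid of the side-chain atoms beyond CB
    (or CA->CB for Ala) is compared with the direction toward the
    centroid of the ``core_residues`` atoms; an angle below 90 degrees
    classifies the side chain as ``"core"``, otherwise ``"exterior"``.
    Gly has no side chain and returns ``None``.
    """
    rid = residue if len(residue) == 3 else (*residue, "")
    res = structure.residue(*rid)
    if res is None:
        raise KeyError(f"no residue {rid}")
    cb = res.atom("CB")
    if cb is None:
        return None
    beyond = [a for a in res.side_chain if a.name != "CB"]
    if beyond:
        direction = np.mean([a.xyz for a in beyond], axis=0) - cb.xyz
    else:
        ca = res.atom("CA")
        if ca is None:
            return None
        direction = cb.xyz - ca.xyz
    core_ids = {r if len(r) == 3 else (*r, "") for r in core_residues}
    core_pts = [
        atom.xyz for aid, atom in structure.atom_ids()
        if aid.residue_id in core_ids
    ]
    if not core_pts:
        raise KeyError("no atoms found for core_residues")
    to_core = np.mean(core_pts, axis=0) - cb.xyz
    cosang = np.dot(direction, to_core) / (
        np.linalg.norm(direction) * np.linalg.norm(to_core)
    )
    return "core" if cosang > 0.0 else "exterior"
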