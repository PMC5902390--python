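"""Deterministic synthetic fixtures with known structural ground truth.

Real variant assessment runs on crystal structures of the integrin
ectodomain; the test surface instead runs on small generated structures
whose interactions are known by construction: a salt-bridge pair at a
requested donor-acceptor distance and angle, a disulfide-bonded Cys
pair, a Ca2+ site with a genu-like coordination shell (two backbone
carbonyls, two side-chain carboxylates, plus the adjacent
disulfide-bonded Cys loop), a packed pocket that clashes only upon a
bulky substitution, and a hairpin/barrel arrangement with side chains
aimed into or out of the core.  Alignments with controlled per-column
conservation and a coding sequence reproducing the alphaIIb
cDNA-to-protein correspondences round out the inputs.

Every generator is a pure function of its parameters (and seed, where
randomness exists at all): identical arguments give byte-identical
output.  Fixtures are heavy-atom only, like the X-ray structures they
stand in for, and inert scaffold residues are kept at least 8 A away
from the engineered feature so they never contaminate an interaction
inventory.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coordinates import GeneModel
from .structure import (
    Atom,
    Chain,
    Residue,
    Structure,
    substitute_residue,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "build_fixture",
    "make_hbond_fixture",
    "make_disulfide_fixture",
    "make_metal_site_fixture",
    "make_clash_pocket_fixture",
    "make_hairpin_fixture",
    "make_msa",
    "make_gene_model",
]

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind + geometry parameters + seed."""

    kind: str
    params: tuple = ()  # sorted (key, value) pairs
    seed: int = 0

    @classmethod
    def create(cls, kind: str, seed: int = 0, **params) -> "FixtureSpec":
        return cls(kind=kind, params=tuple(sorted(params.items())), seed=seed)


_BUILDERS = {}


def build_fixture(spec: FixtureSpec) -> str:
    """Dispatch a :class:`FixtureSpec` to its generator."""
    try:
        builder = _BUILDERS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    kwargs = dict(spec.params)
    if spec.kind == "msa":
        kwargs["seed"] = spec.seed
    return builder(**kwargs)


def _register(kind):
    def deco(fn):
        _BUILDERS[kind] = fn
        return fn
    return deco


def _element_of(atom_name: str) -> str:
    return atom_name.strip()[0]


def _residue(name: str, seq: int, atoms: dict[str, tuple | np.ndarray],
             het: bool = False, elements: dict[str, str] | None = None) -> Residue:
    elements = elements or {}
    return Residue(
        name=name,
        seq=seq,
        atoms=[
            Atom(
                name=an,
                element=elements.get(an, _element_of(an)),
                xyz=np.asarray(xyz, dtype=float),
                het=het,
            )
            for an, xyz in atoms.items()
        ],
    )


def _scaffold(feature_atoms: list[np.ndarray], start_seq: int = 901) -> list[Residue]:
    """Three inert glycines on a line, >= 8 A below the feature."""
    min_y = min(float(p[1]) for p in feature_atoms)
    y = min_y - 10.5
    residues = []
    for i in range(3):
        ca = np.array([-7.0 + 7.0 * i, y, 0.0])
        residues.append(_residue("GLY", start_seq + i, {
            "N": ca + (-0.9, 1.1, 0.3),
            "CA": ca,
            "C": ca + (1.25, 0.8, 0.2),
            "O": ca + (1.8, -0.25, -0.1),
        }))
    return residues


def _finish(chain_residues: list[Residue], chain_id: str = "A") -> str:
    feature = [a.xyz for r in chain_residues for a in r.atoms]
    chain = Chain(id=chain_id, residues=chain_residues + _scaffold(feature))
    return write_pdb(Structure(chains=[chain]))


@_register("hbond_pair")
def make_hbond_fixture(
    donor_acceptor_distance: float = 2.8, angle: float = 160.0
) -> str:
    """Arg/Asp salt-bridge pair with the NH1...OD1 heavy-atom distance
    and the CZ-NH1-OD1 donor angle set exactly as requested.

    The two backbones point away from each other so the engineered
    NH1-OD1 contact is the only donor/acceptor pair within H-bond range.
    Distances outside 2.0-6.0 A raise ``ValueError``.
    """
    d = float(donor_acceptor_distance)
    if not 2.0 <= d <= 6.0:
        raise ValueError(
            f"donor-acceptor distance {d} outside supported range 2.0-6.0 A"
        )
    if not 90.0 <= angle <= 180.0:
        # below ~90 deg the acceptor would fold back over the guanidinium
        # group and collide with the donor residue itself
        raise ValueError(f"angle {angle} outside supported range 90-180 deg")
    theta = np.radians(angle)

    nh1 = np.zeros(3)
    arg = _residue("ARG", 551, {
        "N": (-7.9, 0.9, 3.0),
        "CA": (-6.6, 0.3, 2.7),
        "C": (-6.95, -1.15, 2.45),
        "O": (-6.2, -1.9, 3.0),
        "CB": (-5.75, 1.0, 1.65),
        "CG": (-4.3, 0.7, 1.3),
        "CD": (-3.35, 1.5, 0.45),
        "NE": (-2.0, 1.15, 0.0),
        "CZ": (-1.33, 0.0, 0.0),
        "NH1": nh1,
        "NH2": (-2.0, -1.15, 0.0),
    })

    # acceptor placed at distance d, making the requested angle with the
    # NH1->CZ bond, on the far side from the Arg backbone
    od1 = d * np.array([-np.cos(theta), np.sin(theta), 0.0])
    cg = od1 + (1.22, 0.2, 0.0)
    cb = cg + (1.15, -0.95, 0.35)
    ca = cb + (1.2, -0.55, 0.75)
    c = ca + (-0.45, -1.35, -0.45)
    asp = _residue("ASP", 591, {
        "N": ca + (1.1, 0.8, 0.5),
        "CA": ca,
        "C": c,
        "O": c + (-0.7, -0.95, 0.25),
        "CB": cb,
        "CG": cg,
        "OD1": od1,
        "OD2": cg + (0.6, 1.1, 0.0),
    })
    return _finish([arg, asp])


@_register("disulfide")
def make_disulfide_fixture(
    sg_sg_distance: float = 2.05,
    residue_numbers: tuple[int, int] = (633, 639),
) -> str:
    """Two cysteines with SG atoms at exactly the requested separation,
    backbones diverging in opposite directions (the genu Cys633-Cys639
    loop by default; renumber via ``residue_numbers``)."""
    d = float(sg_sg_distance)
    if d <= 0:
        raise ValueError(f"SG-SG distance must be positive, got {d}")
    na, nb = residue_numbers
    cys_a = _residue("CYS", na, {
        "N": (0.0, 1.55, 4.0),
        "CA": (0.0, 0.55, 2.93),
        "C": (-1.2, -0.3, 3.3),
        "O": (-1.3, -1.5, 3.5),
        "CB": (0.0, 1.05, 1.5),
        "SG": (0.0, 0.0, 0.0),
    })
    cys_b = _residue("CYS", nb, {
        "N": (d, 1.55, -4.0),
        "CA": (d, 0.55, -2.93),
        "C": (d + 1.2, -0.3, -3.3),
        "O": (d + 1.3, -1.5, -3.5),
        "CB": (d, 1.05, -1.5),
        "SG": (d, 0.0, 0.0),
    })
    return _finish([cys_a, cys_b])


_TETRAHEDRAL = np.array([
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)


def _sphere_directions(n: int) -> np.ndarray:
    if n <= 4:
        return _TETRAHEDRAL[:n]
    # deterministic Fibonacci sphere
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t = np.cross(u, ref)
    t /= np.linalg.norm(t)
    return t, np.cross(u, t)


def _carbonyl_ligand_residue(name, seq, u, t, r, extra):
    """Residue whose backbone carbonyl O sits at r*u from the origin ion."""
    o = r * u
    c = o + 1.23 * u
    ca = c + 1.0 * u + 1.1 * t
    atoms = {
        "N": ca + 1.0 * u - 1.05 * t,
        "CA": ca,
        "C": c,
        "O": o,
    }
    atoms.update(extra(ca, u, t))
    return _residue(name, seq, atoms)


def _carboxylate_ligand_residue(name, seq, u, t, r):
    """Asp/Glu whose terminal carboxylate oxygen sits at r*u."""
    o1 = r * u
    cx = o1 + 1.25 * u          # CG (Asp) or CD (Glu)
    if name == "ASP":
        tip = {"OD1": o1, "OD2": cx + 1.25 * t, "CG": cx}
        cb = cx + 1.1 * u + 1.05 * t
    else:  # GLU
        cg = cx + 1.1 * u + 1.05 * t
        tip = {"OE1": o1, "OE2": cx + 1.25 * t, "CD": cx, "CG": cg}
        cb = cg + 1.15 * u - 1.0 * t
    ca = cb + 1.15 * u + (1.0 * t if name == "GLU" else -1.0 * t)
    c = ca + 1.3 * u - 0.8 * t
    atoms = {
        "N": ca + 0.75 * u + 1.25 * t,
        "CA": ca,
        "C": c,
        "O": c + 1.1 * u + 0.55 * t,
        "CB": cb,
    }
    atoms.update(tip)
    return _residue(name, seq, atoms)


@_register("metal_site")
def make_metal_site_fixture(
    n_ligands: int = 4, ligand_distance: float = 2.4
) -> str:
    """Ca2+ ion at the origin with ``n_ligands`` oxygen ligands at exactly
    ``ligand_distance``.

    With four ligands the site emulates the alphaIIb genu Ca2+ loop:
    backbone carbonyls of Cys633 and Val638, side-chain carboxylates of
    Asp636 and Glu673, plus Cys639 disulfide-bonded to Cys633 (SG-SG
    2.05 A).  Other ligand counts build a generic shell of Asp
    carboxylates on evenly spread directions.
    """
    if n_ligands < 0:
        raise ValueError("n_ligands must be >= 0")
    r = float(ligand_distance)
    if n_ligands > 0 and r <= 0:
        raise ValueError(f"ligand distance must be positive, got {r}")
    ion = _residue(
        "CA", 801, {"CA": (0.0, 0.0, 0.0)}, het=True, elements={"CA": "CA"}
    )
    residues: list[Residue] = []
    if n_ligands == 4:
        dirs = _TETRAHEDRAL
        u1, u2, u3, u4 = dirs
        t1, w1 = _frame(u1)

        def cys_side(ca, u, t):
            cb = ca + 0.8 * u + 1.3 * t
            return {"CB": cb, "SG": cb + 0.95 * u + 1.55 * t}

        cys633 = _carbonyl_ligand_residue("CYS", 633, u1, t1, r, cys_side)
        sg = cys633.atom("SG").xyz
        sg_b = sg + 2.05 * w1
        cb_b = sg_b + 1.0 * u1 + 1.5 * w1
        ca_b = cb_b + 0.85 * u1 + 1.25 * w1
        c_b = ca_b + 0.6 * u1 + 1.4 * w1
        cys639 = _residue("CYS", 639, {
            "N": ca_b + 1.2 * u1 - 0.8 * w1,
            "CA": ca_b,
            "C": c_b,
            "O": c_b + 0.45 * u1 + 1.15 * w1,
            "CB": cb_b,
            "SG": sg_b,
        })
        t2, _ = _frame(u2)
        asp636 = _carboxylate_ligand_residue("ASP", 636, u2, t2, r)
        t3, _ = _frame(u3)

        def val_side(ca, u, t):
            cb = ca + 0.8 * u + 1.3 * t
            return {"CB": cb, "CG1": cb + 0.9 * u + 1.2 * t,
                    "CG2": cb + 1.1 * u - 1.05 * t}

        val638 = _carbonyl_ligand_residue("VAL", 638, u3, t3, r, val_side)
        t4, _ = _frame(u4)
        glu673 = _carboxylate_ligand_residue("GLU", 673, u4, t4, r)
        residues = [cys633, asp636, val638, cys639, glu673]
    else:
        for i, u in enumerate(_sphere_directions(n_ligands)):
            t, _ = _frame(u)
            residues.append(
                _carboxylate_ligand_residue("ASP", 101 + i, u, t, r)
            )
    return _finish(residues + [ion])


@_register("clash_pocket")
def make_clash_pocket_fixture() -> str:
    """Pocket where the native Ala is clash-free but a Trp substitution
    produces at least one van der Waals overlap.

    An obstacle residue's CB is placed 2.5 A beyond where the
    maximum-probability Trp rotamer puts its most distal ring atom, so
    the bulky substitution must collide while the native Ala (>= 5 A
    away) and a Gly substitution (no side chain) stay clean.
    """
    import biotite.structure.info as bsinfo

    tmpl = bsinfo.residue("ALA")
    keep = (tmpl.element != "H") & (tmpl.atom_name != "OXT")
    ala = Residue(
        name="ALA",
        seq=100,
        atoms=[
            Atom(name=str(n), element=str(e), xyz=c.astype(float))
            for n, e, c in zip(
                tmpl.atom_name[keep], tmpl.element[keep], tmpl.coord[keep]
            )
        ],
    )
    probe = Structure(chains=[Chain(id="A", residues=[ala])])
    with_trp = substitute_residue(probe, "A", 100, "TRP")
    trp = with_trp.residue("A", 100)
    ca = trp.atom("CA").xyz
    distal = max(trp.side_chain, key=lambda a: np.linalg.norm(a.xyz - ca))
    u = (distal.xyz - ca) / np.linalg.norm(distal.xyz - ca)
    t, _ = _frame(u)
    cb2 = distal.xyz + 2.5 * u
    ca2 = cb2 + 1.53 * u
    c2 = ca2 + 1.52 * (u - t) / np.sqrt(2.0)
    neighbour = _residue("ALA", 101, {
        "N": ca2 + 1.46 * t,
        "CA": ca2,
        "C": c2,
        "O": c2 + 1.23 * u,
        "CB": cb2,
    })
    # fresh Residue copies so probe mutations cannot alias
    ala_out = _residue("ALA", 100, {a.name: a.xyz for a in ala.atoms})
    return _finish([ala_out, neighbour])


@_register("hairpin")
def make_hairpin_fixture() -> str:
    """Barrel-like ring of glycines around the origin plus two valines:
    residue 200 aims its side chain at the barrel core, residue 201 aims
    away — ground truth for side-chain orientation calls."""
    residues = []
    for i in range(6):
        phi = np.pi / 3.0 * i
        ca = 3.0 * np.array([np.cos(phi), np.sin(phi), 0.0])
        c = ca + (0.0, 0.0, -1.52)
        residues.append(_residue("GLY", 301 + i, {
            "N": ca + (0.0, 0.0, 1.46),
            "CA": ca,
            "C": c,
            "O": c - 1.23 * np.array([np.cos(phi), np.sin(phi), 0.0]),
        }))
    cb = np.array([7.5, 0.0, 0.0])
    ca1 = cb + (1.53, 0.0, 0.0)
    c1 = ca1 + (0.9, -1.2, 0.3)
    residues.append(_residue("VAL", 200, {
        "N": ca1 + (0.5, 1.37, 0.0),
        "CA": ca1,
        "C": c1,
        "O": c1 + (1.15, -0.45, 0.05),
        "CB": cb,
        "CG1": cb + (-1.2, 0.95, 0.0),
        "CG2": cb + (-1.2, -0.95, 0.0),
    }))
    cb = np.array([11.0, 6.0, 0.0])
    ca2 = cb + (-1.53, 0.0, 0.0)
    c2 = ca2 + (-0.9, -1.2, 0.3)
    residues.append(_residue("VAL", 201, {
        "N": ca2 + (-0.5, 1.37, 0.0),
        "CA": ca2,
        "C": c2,
        "O": c2 + (-1.15, -0.45, 0.05),
        "CB": cb,
        "CG1": cb + (1.2, 0.95, 0.0),
        "CG2": cb + (1.2, -0.95, 0.0),
    }))
    return _finish(residues)


@_register("msa")
def make_msa(
    n_sequences: int,
    column_conservation: list[float] | tuple[float, ...] | float,
    seed: int = 0,
) -> str:
    """Aligned FASTA with controlled per-column conservation.

    ``column_conservation`` gives, per column, the expected fraction of
    sequences (reference included) carrying the reference residue.  The
    reference is the first sequence; the other rows match independently
    with probability ``(n*p - 1)/(n - 1)`` so the column-wide identity
    fraction is ``p`` in expectation.  Mismatching rows draw a uniformly
    random different residue.  Deterministic for a fixed seed.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    if np.isscalar(column_conservation):
        column_conservation = [float(column_conservation)]
    fractions = [float(p) for p in column_conservation]
    if any(not 0.0 <= p <= 1.0 for p in fractions):
        raise ValueError("conservation fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = len(fractions)
    ref = [AMINO_ALPHABET[j % len(AMINO_ALPHABET)] for j in range(width)]
    rows = [list(ref)]
    for _ in range(n_sequences - 1):
        rows.append(list(ref))
    for j, p in enumerate(fractions):
        if n_sequences == 1:
            continue
        q = np.clip((n_sequences * p - 1.0) / (n_sequences - 1.0), 0.0, 1.0)
        for i in range(1, n_sequences):
            if rng.random() >= q:
                others = AMINO_ALPHABET.replace(ref[j], "")
                rows[i][j] = others[rng.integers(len(others))]
    records = [
        SeqRecord(Seq("".join(row)),
                  id=("ref" if i == 0 else f"seq{i}"), description="")
        for i, row in enumerate(rows)
    ]
    handle = io.StringIO()
    SeqIO.write(records, handle, "fasta")
    return handle.getvalue()


#: Codons cycled through filler positions of the synthetic CDS.
_FILLER_CODONS = ("GCT", "GAA", "CTG", "TCT", "AAA", "GTT", "GAT", "CGT")


def make_gene_model(gene_symbol: str = "ITGA2B") -> GeneModel:
    """Synthetic gene model reproducing the coordinate arithmetic of the
    integrin genes.

    For ITGA2B: 700 codons, signal peptide 31 residues, codon 591 = GAC
    (Asp; c.1772 is its middle A, so c.1772A>C gives Asp591Ala) and codon
    626 = CAG (Gln; c.1878G>C gives Gln626His).  For ITGB3: 250 codons,
    signal peptide 26 residues, codon 145 = GAT (Asp145, mature D119).
    The filler sequence is an arbitrary but fixed cycle of sense codons.
    """
    gene = gene_symbol.upper()
    if gene == "ITGA2B":
        n_codons, signal, fixed = 700, 31, {591: "GAC", 626: "CAG"}
    elif gene == "ITGB3":
        n_codons, signal, fixed = 250, 26, {145: "GAT"}
    else:
        raise ValueError(f"no synthetic model for gene {gene_symbol!r}")
    codons = ["ATG"]
    for i in range(2, n_codons):
        codons.append(_FILLER_CODONS[i % len(_FILLER_CODONS)])
    codons.append("TAA")
    for codon_number, codon in fixed.items():
        codons[codon_number - 1] = codon
    return GeneModel(
        gene_symbol=gene, cds="".join(codons), signal_peptide_length=signal
    )
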