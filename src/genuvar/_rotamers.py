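"""Side-chain rotamer support: chi-angle definitions and a coarse
backbone-independent rotamer table.

Substituted side chains are modelled in the conformation with the
highest library probability, the convention used when visualising
candidate substitutions on a rigid crystal backbone.  The embedded table
holds one modal chi tuple per rotameric state (degrees) with approximate
backbone-independent frequencies; only the ordering matters for the
default maximum-probability selection rule.  A full backbone-dependent
library can be loaded from a whitespace table instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RotamerLibrary", "CHI_ATOMS", "DEFAULT_ROTAMERS"]

#: Atom-name quadruples defining chi1..chiN per residue type.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    # ALA/GLY have no chi angles; PRO's ring is kept as the ideal
    # template conformation rather than rebuilt from chi values.
}

#: (chi tuple in degrees, probability), sorted by decreasing probability.
DEFAULT_ROTAMERS: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "ARG": [((-67.0, 180.0, 180.0, 180.0), 0.22),
            ((-67.0, 180.0, 65.0, 85.0), 0.12)],
    "ASN": [((-65.0, -20.0), 0.33), ((-177.0, -5.0), 0.20)],
    "ASP": [((-70.0, -15.0), 0.51), ((-177.0, 5.0), 0.23)],
    "CYS": [((-65.0,), 0.50), ((-177.0,), 0.26)],
    "GLN": [((-67.0, 180.0, -25.0), 0.36), ((-67.0, -65.0, -40.0), 0.14)],
    "GLU": [((-67.0, 180.0, -10.0), 0.34), ((-67.0, -65.0, -40.0), 0.14)],
    "HIS": [((-63.0, -75.0), 0.30), ((-177.0, -165.0), 0.18)],
    "ILE": [((-65.0, 170.0), 0.60), ((-57.0, -60.0), 0.14)],
    "LEU": [((-65.0, 175.0), 0.59), ((-177.0, 65.0), 0.27)],
    "LYS": [((-67.0, 180.0, 180.0, 180.0), 0.25),
            ((-67.0, 180.0, 180.0, 65.0), 0.10)],
    "MET": [((-65.0, 180.0, 75.0), 0.20), ((-65.0, -65.0, -70.0), 0.17)],
    "PHE": [((-65.0, 85.0), 0.44), ((-177.0, 80.0), 0.33)],
    "SER": [((64.0,), 0.48), ((-65.0,), 0.29)],
    "THR": [((62.0,), 0.49), ((-60.0,), 0.43)],
    "TRP": [((-65.0, 95.0), 0.29), ((-177.0, -105.0), 0.16)],
    "TYR": [((-65.0, 85.0), 0.44), ((-177.0, 80.0), 0.34)],
    "VAL": [((175.0,), 0.73), ((64.0,), 0.15)],
}


@dataclass
class RotamerLibrary:
    """Per-residue rotamer states with a maximum-probability selection rule.

    ``rotamers[resname]`` is a list of ``(chi_tuple, probability)`` pairs
    sorted by decreasing probability; :meth:`top` returns the chi tuple of
    the most probable state (empty for residues without chi angles).
    """

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_ROTAMERS.items()
        }
    )

    def __post_init__(self) -> None:
        for resname, states in self.rotamers.items():
            probs = [p for _, p in states]
            if any(not 0.0 < p <= 1.0 for p in probs):
                raise ValueError(f"{resname}: probabilities must be in (0, 1]")
            if probs != sorted(probs, reverse=True):
                raise ValueError(f"{resname}: rotamers not sorted by probability")
            n_chi = len(CHI_ATOMS.get(resname, []))
            if any(len(chis) != n_chi for chis, _ in states):
                raise ValueError(f"{resname}: chi tuple length != {n_chi}")

    def top(self, resname: str) -> tuple[float, ...]:
        """Chi tuple of the maximum-probability rotamer for a residue type."""
        states = self.rotamers.get(resname.upper())
        if not states:
            return ()
        return states[0][0]

    @classmethod
    def from_file(cls, path: str | Path) -> "RotamerLibrary":
        """Load a library from a whitespace table:
        ``RESNAME chi1 [chi2 ...] probability`` per line, '#' comments.
        """
        rotamers: dict[str, list[tuple[tuple[float, ...], float]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            resname = parts[0].upper()
            *chis, prob = (float(x) for x in parts[1:])
            rotamers.setdefault(resname, []).append((tuple(chis), prob))
        for states in rotamers.values():
            states.sort(key=lambda s: s[1], reverse=True)
        return cls(rotamers=rotamers)
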