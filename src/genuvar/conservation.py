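"""Per-column conservation scoring of aligned protein panels.

The input is an aligned FASTA of orthologues (a species panel) or of
integrin alpha-subunit paralogues; the first sequence is the reference
(human alphaIIb in practice).  Each column is scored by the fraction of
sequences carrying the reference residue, with gaps counted as
mismatches, and optionally by physicochemical similarity classes so that
an Ile/Leu/Val column can be called class-conserved even when strict
identity fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "ConservationProfile",
    "column_identity",
    "is_retained_in_all",
    "classify_conservation",
    "profile_alignment",
    "read_alignment",
    "SIMILARITY_CLASSES",
]

#: Standard physicochemical grouping used for "class-conserved" calls.
#: Replaceable by passing a different iterable of residue sets.
SIMILARITY_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("ILVMA"),  # small/aliphatic hydrophobic
    frozenset("FWY"),    # aromatic
    frozenset("KRH"),    # basic
    frozenset("DE"),     # acidic
    frozenset("STNQ"),   # polar uncharged
    frozenset("C"),
    frozenset("G"),
    frozenset("P"),
)

GAP_CHARS = frozenset("-.")


def _columns(alignment) -> list[str]:
    """Rows of an alignment as upper-case strings."""
    if isinstance(alignment, MultipleSeqAlignment):
        rows = [str(rec.seq) for rec in alignment]
    else:
        rows = [str(s) for s in alignment]
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("sequences are not aligned (unequal lengths)")
    return [r.upper() for r in rows]


def _column(alignment, column: int) -> list[str]:
    rows = _columns(alignment)
    if not 0 <= column < len(rows[0]):
        raise IndexError(
            f"column {column} outside alignment width {len(rows[0])}"
        )
    return [r[column] for r in rows]


def column_identity(alignment, column: int, reference_row: int = 0) -> float:
    """Fraction of sequences matching the reference residue at a column.

    Gaps never match; a gapped reference residue scores 0.0.  Columns are
    0-based.
    """
    col = _column(alignment, column)
    ref = col[reference_row]
    if ref in GAP_CHARS:
        return 0.0
    return sum(1 for res in col if res == ref) / len(col)


def _class_of(residue: str, classes: Iterable[frozenset[str]]):
    for cls in classes:
        if residue in cls:
            return cls
    return None


def is_retained_in_all(
    alignment,
    column: int,
    reference_residue: str,
    similarity_classes: Sequence[frozenset[str]] | None = None,
) -> bool:
    """Is the reference residue retained in every sequence of the panel?

    With ``similarity_classes`` given, retention is judged at the class
    level instead: every residue must belong to the reference residue's
    physicochemical class (so an Ile/Leu/Val column is class-conserved
    while failing the strict test).
    """
    col = _column(alignment, column)
    ref = reference_residue.upper()
    if similarity_classes is None:
        return all(res == ref for res in col)
    cls = _class_of(ref, similarity_classes)
    if cls is None:
        return all(res == ref for res in col)
    return all(res in cls for res in col)


def classify_conservation(
    fraction: float, *, high: float = 0.9, moderate: float = 0.5
) -> str:
    """Map an identity fraction to a qualitative label.

    Defaults: ``high`` for >= 0.9 (e.g. the fully conserved Asp591),
    ``moderate`` for >= 0.5 (relatively well conserved positions such as
    Ile596), ``low`` below (poorly conserved positions such as Pro507).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"identity fraction {fraction} outside [0, 1]")
    if fraction >= high:
        return "high"
    if fraction >= moderate:
        return "moderate"
    return "low"


@dataclass
class ConservationProfile:
    """Per-column conservation summary for one alignment."""

    identity_fraction: list[float]
    strict_conservation: list[bool]
    class_conserved: list[bool]
    residue_classes: list[set[str]] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.identity_fraction)

    def label(self, column: int, **thresholds) -> str:
        return classify_conservation(
            self.identity_fraction[column], **thresholds
        )

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["column\tidentity_fraction\tstrict\tclass_conserved\tlabel"]
        for i in range(self.width):
            lines.append(
                f"{i}\t{self.identity_fraction[i]:.4f}\t"
                f"{int(self.strict_conservation[i])}\t"
                f"{int(self.class_conserved[i])}\t{self.label(i)}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def profile_alignment(
    alignment,
    reference_row: int = 0,
    similarity_classes: Sequence[frozenset[str]] = SIMILARITY_CLASSES,
) -> ConservationProfile:
    """Score every column of an alignment against the reference row."""
    rows = _columns(alignment)
    width = len(rows[0])
    identity, strict, class_ok, res_classes = [], [], [], []
    for i in range(width):
        frac = column_identity(rows, i, reference_row)
        ref = rows[reference_row][i]
        identity.append(frac)
        strict.append(frac == 1.0)
        class_ok.append(
            ref not in GAP_CHARS
            and is_retained_in_all(rows, i, ref, similarity_classes)
        )
        present = {r[i] for r in rows} - GAP_CHARS
        res_classes.append(
            {
                "".join(sorted(cls))
                for res in present
                if (cls := _class_of(res, similarity_classes)) is not None
            }
        )
    return ConservationProfile(identity, strict, class_ok, res_classes)


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA file."""
    return AlignIO.read(str(path), "fasta")
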