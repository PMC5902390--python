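"""Variant parsing and coordinate arithmetic between numbering systems.

Clinical reports describe integrin variants in HGVS coordinates: cDNA
positions counted from the A of the ATG start codon (``c.1772A>C``) and
protein positions counted from the initiator Met including the signal
peptide (``p.Asp591Ala``).  Crystallographic work on the alphaIIb-beta3
ectodomain instead numbers the *mature* chain, after signal-peptide
cleavage: 31 residues are removed from alphaIIb (so Asp591 is D560) and
26 from beta3 (Asp145 is D119).  This module converts between all three
systems and predicts the protein consequence of a coding substitution
under the standard genetic code.

All coordinates are 1-based and inclusive, as in HGVS.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import IUPACData

__all__ = [
    "GeneModel",
    "Variant",
    "parse_variant",
    "codon_of",
    "mature_position",
    "predict_protein_change",
    "classify_nt_change",
    "one_letter",
    "three_letter",
    "read_cds_fasta",
    "read_variant_tsv",
    "VariantFormatError",
    "ReferenceMismatchError",
    "SignalPeptideError",
]

_1TO3 = {k.upper(): v for k, v in IUPACData.protein_letters_1to3.items()}
_3TO1 = {v.upper(): k.upper() for k, v in IUPACData.protein_letters_1to3.items()}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class VariantFormatError(ValueError):
    """A variant string does not match the supported HGVS subset."""


class ReferenceMismatchError(ValueError):
    """The stated reference base/residue disagrees with the gene model."""


class SignalPeptideError(ValueError):
    """An HGVS protein position lies within the cleaved signal peptide."""


def one_letter(aa: str) -> str:
    """Normalise a 1- or 3-letter amino-acid code to upper-case 1-letter."""
    aa = aa.strip()
    if len(aa) == 1:
        return aa.upper()
    if len(aa) == 3 and aa.upper() in _3TO1:
        return _3TO1[aa.upper()]
    raise VariantFormatError(f"unrecognised amino-acid code {aa!r}")


def three_letter(aa: str) -> str:
    """Normalise a 1- or 3-letter amino-acid code to 3-letter (e.g. 'Asp')."""
    return _1TO3[one_letter(aa)]


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence plus the signal-peptide length needed for
    mature-protein numbering.

    The CDS must start with ATG and have a length divisible by 3;
    nucleotide +1 is the A of the start codon.
    """

    gene_symbol: str
    cds: str
    signal_peptide_length: int

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if self.signal_peptide_length < 0:
            raise ValueError("signal_peptide_length must be >= 0")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codon(self, codon_number: int) -> str:
        """The codon (1-based) as a 3-nt string."""
        if not 1 <= codon_number <= self.n_codons:
            raise ValueError(
                f"codon {codon_number} outside CDS (1..{self.n_codons})"
            )
        i = (codon_number - 1) * 3
        return self.cds[i : i + 3]

    def protein(self) -> str:
        """Translation of the CDS (standard code, stop trimmed)."""
        return str(Seq(self.cds).translate(to_stop=True))


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide or single-residue substitution.

    cDNA fields are optional: protein-level variants (``p.Asp591Ala``)
    carry only the protein fields.  ``mature_position`` is filled once a
    gene model supplies the signal-peptide length.
    """

    protein_position_hgvs: int | None = None
    ref_aa: str | None = None  # one-letter
    alt_aa: str | None = None
    cdna_position: int | None = None
    ref_nt: str | None = None
    alt_nt: str | None = None
    mature_position: int | None = None
    gene_symbol: str | None = None
    provenance: str | None = None  # opaque g.-coordinate or source string

    @property
    def is_synonymous(self) -> bool:
        return (
            self.ref_aa is not None
            and self.alt_aa is not None
            and self.ref_aa == self.alt_aa
        )

    def protein_label(self, style: str = "hgvs") -> str:
        """``p.Asp591Ala`` (hgvs) or mature ``D560A`` (mature) label."""
        if self.protein_position_hgvs is None:
            raise ValueError("variant has no protein position")
        if style == "hgvs":
            return (
                f"p.{three_letter(self.ref_aa)}{self.protein_position_hgvs}"
                f"{three_letter(self.alt_aa)}"
            )
        if style == "mature":
            if self.mature_position is None:
                raise ValueError("mature position not set")
            return f"{self.ref_aa}{self.mature_position}{self.alt_aa}"
        raise ValueError(f"unknown style {style!r}")

    def cdna_label(self) -> str:
        if self.cdna_position is None:
            raise ValueError("variant has no cDNA position")
        return f"c.{self.cdna_position}{self.ref_nt}>{self.alt_nt}"


_CDNA_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$", re.IGNORECASE)
_PROT3_RE = re.compile(r"^p\.(?:\()?([A-Za-z]{3})(\d+)([A-Za-z]{3})(?:\))?$")
_PROT1_RE = re.compile(r"^p\.(?:\()?([A-Za-z])(\d+)([A-Za-z])(?:\))?$")


def parse_variant(text: str) -> Variant:
    """Parse a ``c.<pos><ref>><alt>`` or ``p.<ref><pos><alt>`` string.

    Three-letter and one-letter protein codes are both accepted
    (``p.Asp591Ala`` == ``p.D591A``).  Anything else raises
    :class:`VariantFormatError` naming the offending token.
    """
    text = text.strip()
    m = _CDNA_RE.match(text)
    if m:
        pos = int(m.group(1))
        if pos < 1:
            raise VariantFormatError(f"cDNA position must be >= 1 in {text!r}")
        return Variant(
            cdna_position=pos,
            ref_nt=m.group(2).upper(),
            alt_nt=m.group(3).upper(),
            protein_position_hgvs=codon_of(pos),
        )
    m = _PROT3_RE.match(text) or _PROT1_RE.match(text)
    if m:
        try:
            ref = one_letter(m.group(1))
            alt = one_letter(m.group(3))
        except VariantFormatError as exc:
            raise VariantFormatError(f"in {text!r}: {exc}") from exc
        return Variant(
            protein_position_hgvs=int(m.group(2)), ref_aa=ref, alt_aa=alt
        )
    raise VariantFormatError(
        f"unparseable variant {text!r}: expected 'c.<int><NT>><NT>' or "
        "'p.<Aaa><int><Aaa>'"
    )


def codon_of(cdna_position: int) -> int:
    """Codon number containing a cDNA position (+1 = A of ATG).

    ``ceil(position / 3)``: positions 1-3 are codon 1, 1772 is codon 591.
    """
    if cdna_position < 1:
        raise ValueError(f"cDNA position must be >= 1, got {cdna_position}")
    return math.ceil(cdna_position / 3)


def mature_position(gene_model: GeneModel, hgvs_position: int) -> int:
    """Convert HGVS protein numbering to mature-chain numbering.

    Subtracts the signal-peptide length (31 for alphaIIb, 26 for beta3).
    Positions inside the signal peptide have no mature equivalent and
    raise :class:`SignalPeptideError`.
    """
    spl = gene_model.signal_peptide_length
    if hgvs_position <= spl:
        raise SignalPeptideError(
            f"position {hgvs_position} lies within the {spl}-residue signal "
            f"peptide of {gene_model.gene_symbol}"
        )
    return hgvs_position - spl


def hgvs_position(gene_model: GeneModel, mature_pos: int) -> int:
    """Inverse of :func:`mature_position`."""
    if mature_pos < 1:
        raise ValueError(f"mature position must be >= 1, got {mature_pos}")
    return mature_pos + gene_model.signal_peptide_length


def predict_protein_change(gene_model: GeneModel, variant: Variant) -> Variant:
    """Predict the protein consequence of a coding substitution.

    Extracts the affected codon, checks the stated reference base against
    the gene model (raising :class:`ReferenceMismatchError` on
    disagreement), applies the alternate base and translates both codons
    with the standard genetic code.  Returns a new :class:`Variant` with
    protein and mature fields filled; ``ref_aa == alt_aa`` marks a
    synonymous change.
    """
    if variant.cdna_position is None:
        raise ValueError("variant carries no cDNA position")
    pos = variant.cdna_position
    if pos > len(gene_model.cds):
        raise ValueError(
            f"c.{pos} beyond CDS of length {len(gene_model.cds)}"
        )
    found = gene_model.cds[pos - 1]
    if variant.ref_nt is not None and found != variant.ref_nt:
        raise ReferenceMismatchError(
            f"c.{pos} is {found} in {gene_model.gene_symbol}, variant "
            f"states {variant.ref_nt}"
        )
    codon_num = codon_of(pos)
    codon = gene_model.codon(codon_num)
    offset = (pos - 1) % 3
    new_codon = codon[:offset] + (variant.alt_nt or found) + codon[offset + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(new_codon).translate())
    mature = (
        codon_num - gene_model.signal_peptide_length
        if codon_num > gene_model.signal_peptide_length
        else None
    )
    return replace(
        variant,
        protein_position_hgvs=codon_num,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        mature_position=mature,
        gene_symbol=gene_model.gene_symbol,
    )


def classify_nt_change(ref: str, alt: str) -> str:
    """Classify a substitution as ``"transition"`` (purine<->purine or
    pyrimidine<->pyrimidine) or ``"transversion"`` (purine<->pyrimidine).
    """
    ref, alt = ref.upper(), alt.upper()
    for nt in (ref, alt):
        if nt not in _PURINES | _PYRIMIDINES:
            raise ValueError(f"not a DNA base: {nt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}: not a substitution")
    same_class = (ref in _PURINES) == (alt in _PURINES)
    return "transition" if same_class else "transversion"


def read_cds_fasta(
    path: str | Path, gene_symbol: str, signal_peptide_length: int
) -> GeneModel:
    """Build a :class:`GeneModel` from the first record of a FASTA file."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return GeneModel(
        gene_symbol=gene_symbol,
        cds=str(record.seq),
        signal_peptide_length=signal_peptide_length,
    )


def read_variant_tsv(path: str | Path) -> list[Variant]:
    """Parse a one-column TSV/line list of variant strings (``#`` comments
    and blank lines ignored)."""
    variants = []
    for line in Path(path).read_text().splitlines():
        token = line.split("\t")[0].strip()
        if not token or token.startswith("#"):
            continue
        variants.append(parse_variant(token))
    return variants
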