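"""Embedded variant catalog and merged per-variant impact reports.

The catalog transcribes the published missense variants in and around
the alphaIIb genu — the 16 Glanzmann-thrombasthenia-causing
substitutions in the aa471-769 window (index case included), the two
HPA alloantigens, and the three single-allele population-database
variants of the genu Ca2+ loop — together with zygosity, GT type,
mechanism flags and provenance.  These are curated facts, schema
validated on load, never recomputed.

:func:`assess_variant` then composes everything the package can compute
about one variant — coordinate conversions, Grantham distance,
conservation, and the structural before/after inventories — into a
single :class:`ImpactReport`; analyses whose inputs are missing are
reported explicitly as not assessed, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd

from . import conservation as cons
from . import coordinates as coords
from . import physchem
from . import structure as struct

__all__ = [
    "CatalogRecord",
    "ImpactReport",
    "load_catalog",
    "filter_catalog",
    "assign_domain",
    "assess_variant",
    "DOMAIN_BOUNDARIES",
    "MECHANISM_VOCABULARY",
]

#: Approximate domain boundaries in HGVS (signal-peptide-inclusive)
#: numbering, chosen so every published domain assignment in the window
#: (Ala477 propeller, Asp591 thigh, the Cys633-639 loop in the genu,
#: Thr646..Arg755 calf-1, Pro772 at the calf-1/calf-2 interface) falls
#: out correctly.  Config-replaceable; the true structural boundaries
#: are not sharply defined.
DOMAIN_BOUNDARIES: tuple[tuple[int, int, str], ...] = (
    (1, 483, "beta-propeller"),
    (484, 632, "thigh"),
    (633, 644, "genu linker"),
    (645, 769, "calf-1"),
    (770, 778, "calf-1/2 interface"),
)

MECHANISM_VOCABULARY = frozenset({
    "hbond_loss", "hbond_change", "steric", "disulfide_loss",
    "metal_disruption", "splicing_mRNA_decay", "buried_charge",
    "uncertain", "none",
})

CATEGORIES = frozenset({"GT-causing", "HPA", "database-only", "excluded"})
GT_TYPES = frozenset({"I", "II", "n/a"})

#: The index case's scan window (HGVS residue numbers).
SCAN_WINDOW = (471, 769)


def assign_domain(
    protein_position: int,
    boundaries: Sequence[tuple[int, int, str]] = DOMAIN_BOUNDARIES,
) -> str:
    """Domain label for an HGVS protein position (lookup in the
    configurable boundary table; positions outside it are 'other')."""
    for lo, hi, label in boundaries:
        if lo <= protein_position <= hi:
            return label
    return "other"


@dataclass(frozen=True)
class CatalogRecord:
    """One published variant with its clinical/structural annotations."""

    variant: coords.Variant
    gene: str
    domain: str
    category: str
    gt_type: str
    is_index: bool
    zygosity: str
    mechanisms: tuple[str, ...]
    rsid: str | None
    maf_text: str | None
    maf_value: float | None
    provenance: str
    notes: str

    @property
    def protein_change(self) -> str:
        return self.variant.protein_label("hgvs")


class CatalogValidationError(ValueError):
    """The embedded catalog violates its schema invariants."""


def _none_if_dash(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return None if text in ("-", "") else text


def load_catalog(gene_model: coords.GeneModel | None = None) -> list[CatalogRecord]:
    """Load and schema-validate the embedded variant catalog.

    With a gene model supplied, mature-protein positions are filled in
    on every record.  Violated invariants (a GT-causing record outside
    aa471-769, a database-only record without an rsID, an unknown
    mechanism flag) raise :class:`CatalogValidationError`.
    """
    path = resources.files("genuvar").joinpath("data/catalog.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(
            p, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    records = []
    for _, row in table.iterrows():
        variant = coords.parse_variant(row["protein_change"])
        cdna = _none_if_dash(row["cdna_change"])
        if cdna is not None:
            cv = coords.parse_variant(cdna)
            if cv.protein_position_hgvs != variant.protein_position_hgvs:
                raise CatalogValidationError(
                    f"{row['protein_change']}: cDNA {cdna} maps to codon "
                    f"{cv.protein_position_hgvs}"
                )
            variant = coords.Variant(
                protein_position_hgvs=variant.protein_position_hgvs,
                ref_aa=variant.ref_aa, alt_aa=variant.alt_aa,
                cdna_position=cv.cdna_position,
                ref_nt=cv.ref_nt, alt_nt=cv.alt_nt,
            )
        if gene_model is not None and gene_model.gene_symbol == row["gene"]:
            from dataclasses import replace
            variant = replace(
                variant,
                mature_position=coords.mature_position(
                    gene_model, variant.protein_position_hgvs
                ),
                gene_symbol=row["gene"],
            )
        mechanisms = tuple(
            m.strip() for m in str(row["mechanisms"]).split(",") if m.strip()
        )
        maf_value = _none_if_dash(row["maf_value"])
        record = CatalogRecord(
            variant=variant,
            gene=row["gene"],
            domain=assign_domain(variant.protein_position_hgvs),
            category=row["category"],
            gt_type=row["gt_type"],
            is_index=row["is_index"].strip() == "1",
            zygosity=_none_if_dash(row["zygosity"]) or "",
            mechanisms=mechanisms,
            rsid=_none_if_dash(row["rsid"]),
            maf_text=_none_if_dash(row["maf_text"]),
            maf_value=float(maf_value) if maf_value is not None else None,
            provenance=row["provenance"],
            notes=row["notes"],
        )
        _validate_record(record)
        records.append(record)
    return records


def _validate_record(record: CatalogRecord) -> None:
    pos = record.variant.protein_position_hgvs
    if record.category not in CATEGORIES:
        raise CatalogValidationError(
            f"{record.protein_change}: unknown category {record.category!r}"
        )
    if record.gt_type not in GT_TYPES:
        raise CatalogValidationError(
            f"{record.protein_change}: unknown GT type {record.gt_type!r}"
        )
    if record.category == "GT-causing" and not (
        SCAN_WINDOW[0] <= pos <= SCAN_WINDOW[1]
    ):
        raise CatalogValidationError(
            f"{record.protein_change}: GT-causing record outside "
            f"aa{SCAN_WINDOW[0]}-{SCAN_WINDOW[1]}"
        )
    if record.category == "database-only" and not record.rsid:
        raise CatalogValidationError(
            f"{record.protein_change}: database-only record without rsID"
        )
    unknown = set(record.mechanisms) - MECHANISM_VOCABULARY
    if unknown:
        raise CatalogValidationError(
            f"{record.protein_change}: unknown mechanism flags {unknown}"
        )


def filter_catalog(
    records: Sequence[CatalogRecord],
    *,
    region: tuple[int, int] | None = None,
    category: str | None = None,
    gt_type: str | None = None,
    mechanism: str | None = None,
    domain: str | None = None,
    include_index: bool = True,
) -> list[CatalogRecord]:
    """Subset the catalog; an empty predicate returns all records."""
    out = []
    for rec in records:
        pos = rec.variant.protein_position_hgvs
        if region is not None and not region[0] <= pos <= region[1]:
            continue
        if category is not None and rec.category != category:
            continue
        if gt_type is not None and rec.gt_type != gt_type:
            continue
        if mechanism is not None and mechanism not in rec.mechanisms:
            continue
        if domain is not None and rec.domain != domain:
            continue
        if not include_index and rec.is_index:
            continue
        out.append(rec)
    return out


def find_record(
    records: Sequence[CatalogRecord], variant: coords.Variant
) -> CatalogRecord | None:
    for rec in records:
        v = rec.variant
        if (
            v.protein_position_hgvs == variant.protein_position_hgvs
            and v.ref_aa == variant.ref_aa
            and v.alt_aa == variant.alt_aa
        ):
            return rec
    return None


# ---------------------------------------------------------------------------
# impact reports

NOT_ASSESSED = "not assessed"


@dataclass
class ImpactReport:
    """Merged per-variant assessment.

    Sections whose inputs were unavailable hold the reason string
    instead of results; ``rationale`` collects human-readable findings.
    """

    variant: coords.Variant
    grantham_score: float | None = None
    conservation: dict | None = None
    structural: dict | None = None
    catalog: CatalogRecord | None = None
    domain: str | None = None
    not_assessed: dict[str, str] = field(default_factory=dict)
    rationale: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        v = self.variant
        out = {
            "variant": {
                "protein_hgvs": (
                    v.protein_label("hgvs")
                    if v.protein_position_hgvs is not None else None
                ),
                "protein_mature": (
                    v.protein_label("mature")
                    if v.mature_position is not None else None
                ),
                "cdna": v.cdna_label() if v.cdna_position is not None else None,
                "gene": v.gene_symbol,
            },
            "domain": self.domain,
            "grantham_score": self.grantham_score,
            "conservation": self.conservation,
            "structural": self.structural,
            "catalog": None,
            "not_assessed": dict(self.not_assessed),
            "rationale": list(self.rationale),
        }
        if self.catalog is not None:
            rec = self.catalog
            out["catalog"] = {
                "category": rec.category,
                "gt_type": rec.gt_type,
                "is_index": rec.is_index,
                "zygosity": rec.zygosity,
                "mechanisms": list(rec.mechanisms),
                "rsid": rec.rsid,
                "maf": rec.maf_text,
                "provenance": rec.provenance,
                "notes": rec.notes,
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = [f"# Impact report: {d['variant']['protein_hgvs']}"]
        if d["variant"]["cdna"]:
            lines.append(f"- cDNA: {d['variant']['cdna']}")
        if d["variant"]["protein_mature"]:
            lines.append(f"- mature protein: {d['variant']['protein_mature']}")
        if d["domain"]:
            lines.append(f"- domain: {d['domain']}")
        if d["grantham_score"] is not None:
            lines.append(f"- Grantham score: {d['grantham_score']:.0f}")
        for section in ("conservation", "structural", "catalog"):
            if d[section] is not None:
                lines.append(f"\n## {section.capitalize()}")
                lines.append("```json")
                lines.append(json.dumps(d[section], indent=2))
                lines.append("```")
        if d["not_assessed"]:
            lines.append("\n## Not assessed")
            for key, reason in d["not_assessed"].items():
                lines.append(f"- {key}: {reason}")
        if d["rationale"]:
            lines.append("\n## Rationale")
            for line in d["rationale"]:
                lines.append(f"- {line}")
        return "\n".join(lines) + "\n"


def _atomid_str(aid) -> str:
    return str(aid)


def _structural_assessment(
    variant, structure, chain_id, position, criteria, library
) -> tuple[dict, list[str]]:
    res = structure.residue(chain_id, position)
    if res is None:
        raise struct.CannotModelError(
            f"residue {position} not present in chain {chain_id} of the "
            "supplied structure"
        )
    expected = coords.three_letter(variant.ref_aa).upper()
    findings: dict = {"chain": chain_id, "position": position}
    rationale: list[str] = []
    if res.name != expected:
        findings["reference_mismatch"] = (
            f"structure holds {res.name}{position}, variant states {expected}"
        )
    new_aa = coords.three_letter(variant.alt_aa).upper()
    before_hb = struct.detect_hbonds(structure, criteria)
    before_ss = struct.detect_disulfides(structure)
    ions = struct.find_metal_ions(structure)
    after = struct.substitute_residue(
        structure, chain_id, position, new_aa, library=library
    )
    after_hb = struct.detect_hbonds(after, criteria)
    lost, gained = struct.diff_hbonds(before_hb, after_hb, (chain_id, position))
    clashes = struct.detect_clashes(after, focus_residue=(chain_id, position))
    after_ss = struct.detect_disulfides(after)
    findings["hbonds_lost"] = [
        {"donor": _atomid_str(b.donor), "acceptor": _atomid_str(b.acceptor),
         "distance": round(b.distance, 2)} for b in lost
    ]
    findings["hbonds_gained"] = [
        {"donor": _atomid_str(b.donor), "acceptor": _atomid_str(b.acceptor),
         "distance": round(b.distance, 2)} for b in gained
    ]
    findings["clashes"] = [
        {"atoms": f"{_atomid_str(c.atom_a)}--{_atomid_str(c.atom_b)}",
         "overlap": round(c.overlap, 2)} for c in clashes
    ]
    findings["disulfides_before"] = [
        f"{a[0]}/{a[1]}--{b[0]}/{b[1]}" for a, b, _ in before_ss
    ]
    findings["disulfides_after"] = [
        f"{a[0]}/{a[1]}--{b[0]}/{b[1]}" for a, b, _ in after_ss
    ]
    findings["disulfide_lost"] = len(after_ss) < len(before_ss)
    findings["metal_sites"] = []
    for ion in ions:
        disruption = struct.coordination_disruption(
            structure, ion, (chain_id, position, new_aa), library=library
        )
        findings["metal_sites"].append({
            "ion": _atomid_str(ion),
            "shell_before": sorted(
                f"{r[1]}" for r in disruption.shell_before.residues
            ),
            "side_chain_ligand_removed": disruption.side_chain_ligand_removed,
            "disulfide_lost": disruption.disulfide_lost,
            "ion_clash": disruption.ion_clash,
        })
    if lost:
        partners = sorted({
            b.acceptor.resseq if b.acceptor.residue_id != (chain_id, position, "")
            else b.donor.resseq
            for b in lost
        })
        rationale.append(
            f"Substitution of {expected}{position} by {new_aa} results in the "
            f"loss of {len(lost)} structuring H-bond(s) involving residue(s) "
            f"{', '.join(str(p) for p in partners)}."
        )
    if gained:
        rationale.append(
            f"The substitution creates {len(gained)} additional H-bond(s) "
            "within the surrounding loops."
        )
    if clashes:
        rationale.append(
            f"The {new_aa} side chain introduces steric encumbrance "
            f"({len(clashes)} van der Waals overlap(s))."
        )
    if findings["disulfide_lost"]:
        rationale.append(
            "The substitution disrupts a disulfide bridge."
        )
    for site in findings["metal_sites"]:
        if site["side_chain_ligand_removed"]:
            rationale.append(
                f"A side-chain ligand of the {site['ion']} coordination "
                "shell is removed, affecting metal binding."
            )
        if site["ion_clash"]:
            rationale.append(
                f"The new side chain clashes with {site['ion']}, pushing the "
                "ion away by steric encumbrance."
            )
    return findings, rationale


def assess_variant(
    variant: coords.Variant | str,
    *,
    gene_model: coords.GeneModel | None = None,
    structure: struct.Structure | None = None,
    chain: str | None = None,
    structure_position: int | None = None,
    alignment=None,
    column: int | None = None,
    catalog: Sequence[CatalogRecord] | None = None,
    criteria: struct.HBondCriteria | None = None,
    library: struct.RotamerLibrary | None = None,
) -> ImpactReport:
    """Run every available analysis for one variant.

    ``structure_position`` selects the residue number inside the supplied
    structure (structures keep their own author numbering — mature
    numbering for the crystal structures, arbitrary for fixtures); when
    omitted, the HGVS then the mature position is tried.  Analyses whose
    inputs are missing appear under ``not_assessed`` with a reason.
    """
    if isinstance(variant, str):
        variant = coords.parse_variant(variant)
    report = ImpactReport(variant=variant)
    # coordinates
    if variant.cdna_position is not None and gene_model is not None:
        variant = coords.predict_protein_change(gene_model, variant)
        report.variant = variant
    elif (
        gene_model is not None
        and variant.protein_position_hgvs is not None
        and variant.mature_position is None
    ):
        from dataclasses import replace
        report.variant = variant = replace(
            variant,
            mature_position=coords.mature_position(
                gene_model, variant.protein_position_hgvs
            ),
            gene_symbol=gene_model.gene_symbol,
        )
    if variant.protein_position_hgvs is not None:
        report.domain = assign_domain(variant.protein_position_hgvs)
    # physicochemistry
    if variant.ref_aa and variant.alt_aa:
        report.grantham_score = physchem.grantham(variant.ref_aa, variant.alt_aa)
        report.rationale.append(
            f"Physicochemical deviation between {coords.three_letter(variant.ref_aa)} "
            f"and {coords.three_letter(variant.alt_aa)} (Grantham score: "
            f"{report.grantham_score:.0f})."
        )
    else:
        report.not_assessed["grantham"] = "no amino-acid change available"
    # conservation
    if alignment is not None and column is not None:
        frac = cons.column_identity(alignment, column)
        label = cons.classify_conservation(frac)
        strict = cons.is_retained_in_all(
            alignment, column,
            cons._column(alignment, column)[0],
        )
        report.conservation = {
            "column": column,
            "identity_fraction": round(frac, 4),
            "label": label,
            "retained_in_all": strict,
        }
        report.rationale.append(
            f"Position shows {label} conservation across the panel "
            f"(identity {frac:.2f})."
        )
    else:
        report.not_assessed["conservation"] = "no alignment/column provided"
    # structure
    if structure is not None and chain is not None and variant.ref_aa:
        pos = structure_position
        if pos is None:
            for candidate in (
                variant.protein_position_hgvs, variant.mature_position
            ):
                if candidate is not None and structure.residue(
                    chain, candidate
                ) is not None:
                    pos = candidate
                    break
        if pos is None:
            report.not_assessed["structural"] = (
                "variant position not present among the structure's modeled "
                "residues"
            )
        else:
            try:
                findings, rationale = _structural_assessment(
                    variant, structure, chain, pos, criteria, library
                )
                report.structural = findings
                report.rationale.extend(rationale)
            except struct.CannotModelError as exc:
                report.not_assessed["structural"] = f"unmodelable: {exc}"
    else:
        report.not_assessed["structural"] = "no structure provided"
    # catalog
    if catalog is not None and variant.protein_position_hgvs is not None:
        record = find_record(catalog, variant)
        if record is not None:
            report.catalog = record
        else:
            report.not_assessed["catalog"] = "variant not in embedded catalog"
    elif catalog is None:
        report.not_assessed["catalog"] = "no catalog provided"
    return report
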