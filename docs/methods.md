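# Methods

`genuvar` assesses the likely structural consequence of a missense
variant in and around the genu ("knee") of the integrin αIIb subunit,
the fulcrum of the bent resting conformation of the platelet fibrinogen
receptor αIIbβ3. Disease-causing variants in this region (Glanzmann
thrombasthenia) almost uniformly abolish or severely reduce surface
αIIbβ3; the package reproduces the in-silico reasoning used to explain
why: loss of structuring hydrogen bonds, steric encumbrance, disulfide
disruption, buried-charge introduction, and perturbation of the genu
Ca²⁺ coordination shell.

## Coordinate systems

Clinical nomenclature is HGVS: cDNA position counted from the A of the
ATG start codon, protein position counted from the initiator Met with
the signal peptide included. Structural work numbers the mature chain,
after cleavage of the 31-residue αIIb signal peptide (26 residues for
β3); Asp591 in HGVS numbering is D560 of the mature chain. The
`coordinates` module performs these conversions and predicts the protein
consequence of a coding substitution with the standard genetic code,
cross-checking the stated reference base against the gene model. Codon
number is `ceil(cdna_position / 3)`. Only single-nucleotide
substitutions are computed objects; splice/intronic partner alleles are
carried as verbatim annotation strings because their mapping is not
derivable from a CDS alone. All public coordinates are 1-based.

## Grantham distance

Physicochemical deviation between the reference and substituted residue
is the Grantham (1974) distance

D_ij = ρ·[α(c_i−c_j)² + β(p_i−p_j)² + γ(v_i−v_j)²]^½

over side-chain composition *c*, polarity *p* and molecular volume *v*,
with the original weights α = 1.833, β = 0.1018, γ = 0.000399 and scale
ρ = 50.723 (chosen by Grantham so the mean over the 190 residue pairs is
100; the embedded constants realize a mean of 99.87). Scores are
reported as integers, rounded half away from zero, matching published
matrices. A handful of cells of the widely circulated printed matrix
differ from the formula by one unit (its own rounding); the three scores
this package is anchored on (Asp/Ala 126, Ile/Thr 89, Pro/Arg 103) are
reproduced exactly.

## Conservation

Panels (species orthologues, or the integrin α-subunit paralogues) are
supplied as pre-aligned FASTA; the first row is the reference. Per
column the score is the fraction of sequences carrying the reference
residue, gaps counting as mismatches; a gapped reference column scores
0. Qualitative labels use configurable thresholds, high ≥ 0.9 and
moderate ≥ 0.5 — the source literature uses only qualitative wording
("highly conserved", "relatively well conserved", "poorly conserved"),
so the cutpoints are design choices exposed in the API. A class-level
retention test uses a standard physicochemical grouping
({ILVMA}, {FWY}, {KRH}, {DE}, {STNQ}, {C}, {G}, {P}), replaceable per
call, so an Ile/Leu/Val column can be called class-conserved while
failing strict identity. No phylogenetic weighting is applied; panel
membership is the caller's responsibility.

## Structural model

Structures are parsed from PDB text (via gemmi) into a minimal
chain→residue→atom model. Metal ions are kept, waters dropped by
default, and alternate locations resolved to the highest-occupancy
conformer (ties to conformer 'A'). Structures keep their file's author
numbering; no offset arithmetic happens inside the structure code — the
coordinates module owns HGVS↔mature conversion.

**Substitution.** A variant is modelled by replacing one residue's side
chain on a rigid backbone: the backbone atoms (N, CA, C, O, OXT) keep
bit-identical coordinates, and an ideal side chain of the new type is
taken from the chemical-component dictionary templates shipped with
biotite, superimposed on the local N/CA/C frame (Kabsch), and rotated to
the χ angles of the library's maximum-probability rotamer. The embedded
rotamer table is a coarse backbone-independent set — one modal χ tuple
(plus alternates) per residue type with approximate frequencies; only
the ordering matters for max-probability selection, and a full
backbone-dependent library can be loaded from a text table. Proline's
ring is kept in template conformation rather than rebuilt from χ values.
No neighbour repacking, minimization or dynamics is performed: the
question asked is the short-range, rigid-backbone one.

**Hydrogen bonds.** Crystal structures carry no hydrogens, so an H-bond
is a heavy-atom criterion: a donor atom (backbone N; side-chain N;
hydroxyl O; thiol S — name-based sets, configurable) within 3.5 Å of an
acceptor atom (carbonyl/carboxylate/hydroxyl O; His ring N; Met S),
with the angle at the donor (nearest bonded heavy atom – donor –
acceptor) ≥ 90° where computable. 3.5 Å is the conventional cutoff; the
source figures also draw longer "potential" contacts, so a second,
looser tier (3.5 Å up to a configurable bound, default off) is reported
with tier `potential`. Intra-residue pairs and covalently connected
backbone atoms of sequence-adjacent residues are excluded, and each
unordered atom pair is reported once. Differencing two inventories
around a focus residue restricts to bonds touching the focus or its
pre-substitution partners; "identity" here means diffing detections of
the unchanged structure (a same-type rebuild idealizes the side chain by
design and may legitimately shift marginal bonds).

**Clashes.** A pair of atoms clashes when their distance is below the
sum of van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å; Ca²⁺
2.31 Å) minus an overlap tolerance, default 0.4 Å — the usual "bump"
convention. Excluded as bonded: intra-residue pairs, backbone atoms of
adjacent residues, SG/CB pairs across a detected disulfide, and
metal–ligand pairs within the coordination cutoff (dative bonds, not
steric contacts). The clash count is monotone non-increasing in the
tolerance.

**Disulfides and metal sites.** A disulfide is a Cys SG–SG pair within
2.3 Å. A coordination shell collects oxygen atoms (the physiological
Ca²⁺ ligand element; configurable) within 3.0 Å of a metal ion,
classified backbone-carbonyl (atom name O/OXT) versus side-chain. The
disruption report for a substitution at a metal site recomputes shell
and disulfides after the substitution and flags: a side-chain ligand
removed (e.g. Glu→Lys deletes a carboxylate), a disulfide lost (e.g.
Cys→Ser), and a new clash between the rebuilt side chain and the ion
(steric displacement of the metal). A substitution at a
backbone-carbonyl ligand leaves the backbone contribution intact and
raises no ligand flag.

**Orientation.** For β-sandwich cores, a side chain is classified
`core` when the CB→side-chain-centroid vector (CA→CB for Ala) makes an
angle below 90° with the direction toward the centroid of the
user-designated core residues; Gly is explicitly undefined.

## Synthetic fixtures

Because the crystal structures cannot be redistributed and tests must
run offline, the `synthetic_data` module generates small PDB structures
whose ground truth is known by construction and re-derivable by a
brute-force pairwise-distance pass:

- an Arg/Asp salt-bridge pair with the NH1⋯OD1 distance and the
  CZ–NH1–OD1 angle placed exactly as requested (2.0–6.0 Å, 90–180°),
  with backbones diverging so it is the only donor/acceptor pair in
  range;
- a Cys pair with exact SG–SG separation (renumberable, e.g. to
  705/718);
- a Ca²⁺ site with oxygen ligands at exact radius; the four-ligand form
  mirrors the genu loop (backbone carbonyls of 633 and 638, side-chain
  carboxylates of 636 and 673, plus the 633–639 disulfide);
- a pocket whose obstacle is placed 2.5 Å beyond the most distal atom
  of the top-rotamer Trp at the central position, so the native Ala is
  clash-free, Trp must clash, and Gly cannot;
- a barrel-like ring with one valine aimed into and one out of the
  core;
- alignments whose per-column identity fraction is controlled in
  expectation (non-reference rows match with probability
  (np−1)/(n−1));
- a synthetic gene model: 700 codons for ITGA2B (signal peptide 31,
  codon 591 = GAC, codon 626 = CAG, so c.1772A>C → Asp591Ala and
  c.1878G>C → Gln626His fall out of translation, not lookup) and 250
  codons for ITGB3 (signal peptide 26, codon 145 = GAT).

All generators are pure functions of (parameters, seed): identical
inputs give byte-identical files. Fixtures are heavy-atom only, single
chain, occupancy 1.00, B 0.00; inert glycine scaffolds sit ≥ 8 Å from
the engineered feature. Coordinates are written at 1 mÅ precision with
one end of each calibrated distance at the origin, keeping realized
distances within 1e-3 Å of request. What the fixtures do **not**
emulate: realistic folds, packing density, crystallographic disorder,
hydrogens, or the cooperative H-bond networks of a real β-sandwich —
passing fixture tests demonstrates the detectors' geometric
correctness, not biological accuracy on real ectodomain structures,
which additionally depends on the crystal model quality and the rigid
side-chain approximation.

## Variant catalog

The published variants of the region are embedded as a versioned TSV:
the 16 disease-causing substitutions in the aa471–769 window (index
case Asp591Ala included), the two HPA alloantigens (Ser503Asn/HPA-24b,
Thr650Met/HPA-20b), the three single-allele population-database
variants of the genu Ca²⁺ loop (Cys633Ser, Asp636Asn, Glu673Lys), and
Pro772Arg recorded as excluded (calf-1/calf-2 interface, outside the
window). Zygosity, GT type (I = absent αIIbβ3, II = severely reduced),
mechanism flags, rsIDs and minor-allele frequencies are curated
annotations — frequencies are stored verbatim (including one ambiguous
"0.00002/8") with a parsed numeric only where unambiguous, and external
predictor verdicts are never recomputed. The schema is validated on
load: GT-causing records must lie in the window, database-only records
must carry an rsID, mechanism flags must come from the fixed
vocabulary. Domain labels come from a configurable boundary table
(β-propeller ≤ 483, thigh 484–632, genu linker 633–644, calf-1
645–769, calf-1/2 interface 770–778, HGVS numbering) chosen so every
published domain placement falls out correctly; the true structural
boundaries are approximate and user-replaceable.

## Numerical and design notes

- Rounding: Grantham integers round half away from zero; PDB output is
  fixed-format at 3 decimals.
- Altloc ties resolve to conformer 'A'; duplicate atom names within a
  residue are rejected.
- Degenerate inputs: empty structures, all-gap alignment columns,
  positions inside the signal peptide, residues missing backbone atoms
  and Gly orientation all raise or return explicit sentinels rather
  than guessing.
- The O(n²) oracle used in the tests shares only the published cutoffs
  with the detectors, never code; detectors use spatial trees, the
  oracle plain loops.
- Problem sizes: fixtures are 30–80 atoms, alignments up to ~20 rows —
  sizes at which exhaustive enumeration is exact and instant, chosen
  because the ground-truth arguments are combinatorial, not
  statistical.

## Known limitations

Rigid-backbone, single-rotamer substitution cannot capture backbone
relaxation, neighbour repacking or the long-range/allosteric effects
that molecular-dynamics studies report for calf-1 substitutions; those
are out of scope by design. Splice effects (the Gln626His allele acts
primarily through exon skipping and mRNA decay) are catalog mechanism
flags, not predictions. The package does not classify pathogenicity; it
inventories structural consequences.
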