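# genuvar

Structural impact assessment of missense variants in and around the
**genu** of the integrin αIIb subunit — the "knee" between the thigh and
calf-1 domains that acts as the fulcrum of the bent, resting
conformation of the platelet fibrinogen receptor αIIbβ3. Missense
variants here cause Glanzmann thrombasthenia (GT), a recessive bleeding
disorder with absent (type I) or severely reduced (type II) surface
αIIbβ3.

The package is for people who curate or analyse *ITGA2B* variants and
want the in-silico part of that workflow to be reproducible code rather
than a manual modelling session:

- **coordinates** — parse HGVS-style variants (`c.1772A>C`,
  `p.Asp591Ala`), map cDNA → codon → HGVS protein → mature-chain
  numbering (αIIb subtracts its 31-residue signal peptide, β3 its 26),
  and predict protein consequences under the standard genetic code.
- **physchem** — Grantham physicochemical distance
  D = ρ·[α·Δc² + β·Δp² + γ·Δv²]^½ over side-chain composition,
  polarity and molecular volume, with the original 1974 constants.
- **conservation** — per-column identity and class-level retention
  across species/paralog panels from aligned FASTA.
- **structure** — parse PDB, replace one residue's side chain with the
  maximum-probability rotamer of the new type on a rigid backbone, and
  inventory hydrogen bonds, van der Waals clashes, disulfide bridges,
  Ca²⁺ coordination shells and side-chain orientation before vs after.
- **catalog_report** — the embedded, schema-validated catalog of the
  published variants of the region (16 GT-causing in aa471–769, 2 HPA
  alloantigens, 3 population-database genu variants) and the merged
  per-variant `ImpactReport`.
- **synthetic_data** — deterministic PDB/alignment/CDS fixtures with
  construction-level ground truth, so the whole pipeline is testable
  offline.

## Worked example

The index-case variant, a homozygous transversion producing an
Asp→Ala substitution in a thigh-domain loop:

```sh
$ genuvar grantham Asp Ala
126

$ genuvar report --variant p.Asp591Ala
# Impact report: p.Asp591Ala
- mature protein: D560A
- domain: thigh
- Grantham score: 126
...
## Rationale
- Physicochemical deviation between Asp and Ala (Grantham score: 126).
```

The score 126 flags a physicochemically radical change (the scale
averages 100 over all residue pairs); D560A is the same variant in
mature-chain numbering, and the catalog section reports its curated
annotations (GT type I, homozygous, rs778608263, H-bond-loss
mechanism).

With a structure, the report adds the before/after interaction diff.
On the salt-bridge fixture (an Arg551/Asp591 pair engineered at 2.8 Å):

```sh
$ genuvar fixture hbond_pair --out pair.pdb
$ genuvar impact --pdb pair.pdb --chain A --sub "591:ASP>ALA"
...
  "hbonds_lost": [
    {"donor": "A/ARG551/NH1", "acceptor": "A/ASP591/OD1", "distance": 2.8}
  ],
  "hbonds_gained": [],
  "clashes": [],
...
```

i.e. substituting the aspartate by alanine removes the structuring
H-bond it made — the rigid-backbone analogue of the reasoning used to
explain why such variants block αIIbβ3 biosynthesis. The same API is a
Python library:

```python
from genuvar import assess_variant, load_catalog, read_pdb

report = assess_variant("p.Asp591Ala", catalog=load_catalog())
print(report.grantham_score)   # 126.0
print(report.domain)           # thigh
```

## Scope notes

External pathogenicity predictors (SIFT/PolyPhen/MutationTaster),
database allele frequencies and splice/mRNA-decay effects are stored as
curated catalog annotations, never recomputed. No energy minimization,
neighbour repacking or molecular dynamics: the structural assessment is
deliberately the short-range, rigid-backbone one. See
`docs/methods.md` for the full model description, parameter defaults
and limitations.
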