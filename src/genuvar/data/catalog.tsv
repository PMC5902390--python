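# Published missense variants in and around the integrin alphaIIb genu (ITGA2B),
# transcribed from the primary clinical/structural literature on Glanzmann
# thrombasthenia in the aa471-769 window plus the HPA and population-database
# variants discussed alongside them.  SIFT/PolyPhen/MutationTaster verdicts,
# zygosity and MAFs are stored as annotations, never recomputed; MAF strings
# are kept verbatim (maf_text) with a parsed numeric (maf_value) only where
# unambiguous.  Categories: GT-causing (disease-causing in the window),
# HPA (alloantigen, expression unaffected), database-only (single-allele
# population variants of the genu Ca2+ loop), excluded (outside the window).
# Note: the source literature counts nine disease-causing calf-1 missense
# variants in the genu-proximal region while naming fewer in the main text;
# only named variants are recorded here, none invented.
gene	protein_change	cdna_change	category	gt_type	is_index	zygosity	mechanisms	rsid	maf_text	maf_value	provenance	notes
ITGA2B	p.Ala477Pro	-	GT-causing	II	0	homozygous	hbond_loss	-	-	-	Fu et al.	3rd beta-strand of 7th propeller blade; Pro weakens H-bonds linking strands 3-4 of blade 7; surface expression 14% of wild type in CHO cells; ER retention
ITGA2B	p.Ser503Asn	-	HPA	n/a	0	-	none	-	-	-	Jallu et al.	HPA-24b alloantigen; expression unaffected
ITGA2B	p.Pro507Arg	-	GT-causing	I	0	homozygous	buried_charge	-	-	-	Peretz et al.	poorly conserved; partially buried loop tip; Grantham 103; prediction tools disagree
ITGA2B	p.Ile518Asp	-	GT-causing	I	0	compound heterozygous (with c.1946+3G>T splice variant)	buried_charge	-	-	-	Nurden et al.	hydrophobic thigh beta-barrel position; charged Asp introduces deep instability
ITGA2B	p.Arg551Trp	-	GT-causing	I	0	homozygous (two patients, Southern India)	hbond_loss,steric	-	-	-	Nelson et al.	mutation hotspot; loss of multiple structuring H-bonds plus steric encumbrance from Trp
ITGA2B	p.Arg551Gln	-	GT-causing	I	0	homozygous (three unrelated families)	hbond_loss	-	-	-	Haghighi et al.; Vijapurkar et al.	mutation hotspot; loss of multiple structuring H-bonds
ITGA2B	p.Ala581Asp	-	GT-causing	I	0	heterozygous (second defect unidentified)	buried_charge	-	-	-	D'Andrea et al.	hydrophobic thigh beta-barrel position; charged Asp introduces deep instability
ITGA2B	p.Asp591Ala	c.1772A>C	GT-causing	I	1	homozygous	hbond_loss	rs778608263	0.000008354	0.000008354	index case (Wertz et al.)	transversion in exon 18; NC_000017.11:g.44379795T>G; mature D560A; shares H-bonds with Arg551, Leu593 and Ser594, lost on Ala substitution; Grantham 126
ITGA2B	p.Ile596Thr	-	GT-causing	I	0	homozygous or compound heterozygous (with IVS29(+2)T>C, c.3091delC or Glu355Lys)	hbond_change	-	-	-	French & Coller; Jallu et al.; Ruan et al.; Sandrock et al.	likely mutational hotspot; Thr -OH 3.4 A from Arg551 competes for H-bonds with Asp542, Ser594 and Asp591; Grantham 89
ITGA2B	p.Gln626His	c.1878G>C	GT-causing	I	0	homozygous (four European studies; possible founder effect)	splicing_mRNA_decay	-	-	-	Jallu et al.; Nurden et al.; Pillitteri et al.; Sandrock et al.	c.1878G>C primarily affects splicing: exon skipping and mRNA decay; recombinant His626 integrin expresses normally; Gln626-Asn722 H-bond clasp position
ITGA2B	p.Cys633Ser	-	database-only	n/a	0	single allele (population database)	disulfide_loss	rs1126555	no frequency data	-	Ensembl	disrupts the Cys633-Cys639 disulfide of the genu Ca2+ loop; backbone carbonyl coordinates Ca2+ (retained)
ITGA2B	p.Asp636Asn	-	database-only	n/a	0	single allele (population database)	uncertain	rs749873100	0.00004	0.00004	Ensembl	side chain coordinates the genu Ca2+
ITGA2B	p.Glu673Lys	-	database-only	n/a	0	single allele (population database)	metal_disruption	rs368974006	0.00002/8	-	Ensembl	side-chain Ca2+ ligand contributed from calf-1; Lys pushes the Ca2+ away by steric encumbrance
ITGA2B	p.Thr646Ala	-	GT-causing	I	0	homozygous	uncertain	-	-	-	Tokgoz et al.	points to the exterior; effect of smaller Ala difficult to predict
ITGA2B	p.Thr650Met	-	HPA	n/a	0	-	none	-	-	-	Peterson et al.	HPA-20b alloantigen; expression unaffected
ITGA2B	p.Leu684Arg	-	GT-causing	I	0	heterozygous (second allele unidentified)	steric,buried_charge	-	-	-	Pillitteri et al.	hydrophobic beta-barrel core; larger polar residue introduces steric encumbrance; highly destabilizing
ITGA2B	p.Cys705Arg	-	GT-causing	II	0	homozygous or compound heterozygous (multiple European families; probable founder defect)	disulfide_loss	-	-	-	Gonzalez-Manchon et al.; D'Andrea et al.; Mitchell et al.; Jallu et al.; Nurden et al.	loss of the Cys705-Cys718 disulfide destabilizes the calf-1 beta-barrel, exposing the hydrophobic core
ITGA2B	p.Cys705Leu	-	GT-causing	I	0	heterozygous (second allele unidentified)	disulfide_loss	-	-	-	Santoro et al.	<5% surface integrin; same disulfide loss as Cys705Arg
ITGA2B	p.Leu752Val	-	GT-causing	I	0	homozygous (coexpressed with Arg755Pro; rare haplotype)	uncertain	-	-	-	D'Andrea et al.	weakly conserved; independent pathogenicity unresolved
ITGA2B	p.Arg755Pro	-	GT-causing	I	0	homozygous	uncertain	-	-	-	D'Andrea et al.; Vijapurkar et al.	side chain aligns toward the exterior of the beta-barrel, limiting short-range effects; long-range dynamics implicated
ITGA2B	p.Arg755Gln	-	GT-causing	I	0	heterozygous (siblings also carrying two ITGB3 variants)	uncertain	-	-	-	Nurden et al. (cases 35a,b)	role in the phenotype difficult to assign
ITGA2B	p.Pro772Arg	-	excluded	n/a	0	-	none	-	-	-	literature	calf-1/calf-2 interface (erroneously placed within calf-2 in the original report); outside the aa471-769 window; not considered further
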