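# onkointerp

A variant-interpretation toolkit for precision oncology.  It takes the
sequence variants of a tumor sample — typed as free-text queries or uploaded
as VCF/MAF files — and produces what a molecular tumor board needs to read:
a variant table ranked by estimated pathogenicity, a treatment table of
evidence-backed therapy options, and a per-residue structural analysis of
the mutated protein site.  It is a library first (every step is a plain
Python function) with a thin `onkointerp` command line on top.

## What it computes

**Multi-level variant parsing.**  Queries are accepted at DNA level
(`chr12:g.25245350C>T`), transcript level (`NM_004985.5:c.35G>A`), and
protein level (`KRAS:p.G12D`, the knowledge-base shorthand `KRAS G12D`,
and three-letter forms `p.Gly12Asp`), plus VCF, MAF, and plain-list files.
Gene fusions given as two breakpoints are checked for reading-frame
compatibility: a fusion is in frame iff the retained 5'-partner coding
length mod 3 equals the 3'-partner's codon offset at its junction.

**Clinical-evidence harmonization.**  Evidence tables in three source
dialects (CIViC-like, OncoKB-like, MetaKB-like) are normalized to a common
schema: source evidence codes map to AMP/ASCO/CAP tier letters A–D through
an editable configuration; response values map to
sensitive/resistant/unknown (OncoKB-style `R1`/`R2` → resistant,
`1`/`2`/`3A`/`3B` → sensitive; CIViC-style significance containing
"Sensitivity"/"Resistance"); multi-drug "substitutes" entries are split
into separate single-drug options; cancer types are mapped to
OncoTree-style main types by exact-then-fuzzy matching; drugs are
classified from a drug-class table.

**Five-level therapy matching.**  A knowledge-base biomarker can match a
patient variant as (1) the exact exchange, (2) a different exchange at the
same residue, (3) any exchange at the residue, (4) a variant in the same
exon, or (5) any mutation in the gene.  All levels are searched and
returned together; duplicates identical on (drug, cancer entity, evidence
level, response, citation ID) are merged across sources.  Matched
treatments aggregate into nested sunburst-style hierarchies over any layer
order ending in citation IDs.

**ACMG five-class classification.**  A deterministic subset of the
ACMG/AMP evidence criteria (PVS1, PS1, PM1/PM2/PM5, PP3/PP5, BA1, BS1,
BP4/BP6) is evaluated from retrieved annotations — population allele
frequency, predictor scores, ClinVar-style assertions — and combined into
pathogenic / likely pathogenic / VUS / likely benign / benign, with a full
derivation trace per variant.

**Protein structural context.**  From a wild-type structure (PDB ATOM
records, AlphaFold-style confidence in the B-factor column) the toolkit
computes per-residue accessible surface area by Shrake–Rupley quadrature
and relative accessibility RSA = ASA / MaxASA; Euclidean Cα distances to
the mutated residue, d_i = √((x_i−x_m)² + (y_i−y_m)² + (z_i−z_m)²);
three-state secondary structure (H/E/C) by Kabsch–Sander hydrogen-bond
detection; substitution physicochemistry (Δweight, charge, polarity,
aromaticity, helix breakers, BLOSUM62); disulfide-bond and salt-bridge
candidates gained or lost; and spatially close known variants — exposing
sites that are far in sequence but close in the folded structure.

## Worked example

Generate the packaged toy fixtures and run the pipeline:

```
onkointerp fixtures --seed 1 --out demo
onkointerp annotate --in demo/variants.vcf --format vcf --kb demo/kb \
    --annotations demo/annotations.tsv --cancer-types demo/cancer_types.tsv \
    --drug-classes demo/drug_classes.tsv --out demo/out
```

prints the stage summary

```
{"parsed": 3, "skipped": 0, "classified": 3, "variant_rows": 3, "treatment_rows": 10, "kb_records": 40}
```

i.e. all three VCF records were parsed, classified, and exported, and ten
merged treatment options were found.  `demo/out/variants.csv` is sorted
pathogenic-first; `demo/out/treatments.csv` holds the treatment table
(biomarker, match type, drugs, drug classification, evidence level,
response type, citation ID).  Its RET row shows the value of the broader
match types: the patient variant RET M918T has no exact entry in the toy
knowledge base, but the gene-level record is retrieved and carries its
payload —

```
RET M918T,gene_level,selpercatinib,RET tyrosine kinase inhibitor,A,sensitive,CIT105
```

a tier-A, sensitive RET-inhibitor option found via "any mutation in gene".

For the protein context of a mutated site:

```
onkointerp protein --structure demo/helix.pdb --variant KRAS:p.G12D \
    --score 0.8 --out demo/protein
```

prints the rule-based context summary for the site, e.g.

```
residue 12 (G): ss=H, rsa=0.49 (protein mean 0.58), domain=none -> indeterminate context
```

and writes the aligned per-residue feature tracks (ASA, RSA, Cα distance,
secondary structure, domain, binding probability) as TSV and JSON.

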