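# Methods

This note documents the models, rules, parameters, and numerical choices
behind `onkointerp`, and what the synthetic fixtures do and do not emulate.

## Variant model

Variants live at one of three nomenclature levels (DNA `g.`, transcript
`c.`, protein) with 1-based coordinates throughout, matching VCF and HGVS
conventions.  Chromosome labels are stored without the `chr` prefix; the
reference genome is a metadata label (default `hg38`) and alleles are never
validated against a genome sequence — that would require an external FASTA
and is out of scope.  Three-letter amino-acid codes and parenthesized
protein changes are normalized at parse time; the bare shorthand
`GENE AA###AA` is accepted because knowledge bases print biomarkers that
way.  MAF input requires only six columns (Hugo_Symbol, Chromosome,
Start_Position, Reference_Allele, Tumor_Seq_Allele2, HGVSp_Short); a MAF
row yields a DNA-level variant whose protein fields are additionally
populated from HGVSp_Short, since downstream therapy matching operates on
the protein change.

**Fusion frame rule.**  With `breakpoint_a` the last retained base of the
5' partner and `breakpoint_b` the first retained base of the 3' partner,
the fusion is in frame iff

    (retained 5' coding length) mod 3 == (3' codon offset at its junction) mod 3,

computed strand-aware over the exon ∩ CDS positions of each transcript in
transcript orientation.  Breakpoints in UTRs, introns, or outside the
transcript give `undetermined` rather than an error, because no frame
statement is possible there.

## Evidence harmonization

Each source dialect is a TSV with its own column names and vocabularies.
Normalization order is fixed: response type → evidence level → substitutes
splitting → cancer type → drug classification.  Raw fields are always
retained next to their normalized forms, which makes the pipeline
idempotent (re-normalizing normalized records recomputes from the same
raws) and lossless.

* **Response types.**  OncoKB-style codes `R1`, `R2` → resistant and `1`,
  `2`, `3A`, `3B` → sensitive; CIViC-style significance strings containing
  "Sensitivity" or "Resistance" map accordingly; MetaKB-style descriptive
  associations are mapped by keyword stems (`sensitiv-`/`respon-` →
  sensitive, `resist-` → resistant).  Everything else is `unknown` — never
  an error.
* **Evidence levels.**  Source codes map to AMP/ASCO/CAP tier letters A–D
  through `data/evidence_level_mapping.cfg`, a flat, user-replaceable
  key-value file following the published cross-knowledgebase harmonization
  approach.  The exact cell-by-cell table is not reprinted anywhere
  authoritative in our inputs, so the shipped mapping is a documented
  default (CIViC A–E → A, B, C, D, D; OncoKB 1/2 → A, 3A/3B → B, 4 → D,
  R1 → A, R2 → C).  Unmapped codes leave the tier unset with a warning.
* **Substitutes.**  A record listing k interchangeable drugs becomes k
  single-drug records; drug multisets are conserved by construction.
* **Cancer types.**  Exact case-insensitive matching on labels, synonyms,
  and main-type names always wins.  Otherwise fuzzy matching uses
  normalized edit similarity `1 − Levenshtein(a, b) / max(|a|, |b|)` with
  default threshold 0.85, ties broken by lexicographically smallest main
  type, and `"Unmatched"` below threshold.  The metric and threshold are
  configurable choices — only "exact and fuzzy matching" is specified by
  the approach we follow — and the Levenshtein distance is computed with
  edlib.
* **Drug labels** are trimmed, case-folded, and whitespace-collapsed
  before any comparison; this normalized label is also the merge key
  component used downstream.

## Therapy matching

The five match types, in decreasing specificity: exact exchange; differing
exchange at the same residue; arbitrary exchange at the residue
(positional spec like `G12`); same exon; gene level (`mutation`).  A
record matching several rules is labeled with the most specific one, and
all levels are returned together — broader evidence is informative even
when an exact hit exists, so nothing is suppressed.  Exon matching maps
the variant's residue to the exon containing the first base of its codon
via a caller-supplied transcript annotation; we deliberately require an
explicit transcript rather than guessing a canonical one.  Merging
collapses records identical on (sorted drug labels, cancer main type,
tier, response, citation ID), unions their sources, and keeps the most
specific match type; output order is sorted by key, making merging
idempotent and order-invariant.  Hierarchies group treatments over an
arbitrary layer order; the citation layer is always the leaf (appended if
omitted), so leaf counts are conserved under layer permutations.

## ACMG classification

Only criteria computable from the annotation bundle are implemented:
PVS1 (null variant in an LoF gene), PS1 (same change known pathogenic),
PM5 (different pathogenic change at the residue), PM1 (hotspot/functional
domain), PM2 (absent or rarer than the rare cutoff), PP3/BP4 (predictor
consensus), PP5/BP6 (reputable-source assertion), BA1 (common), BS1
(greater than expected for the disorder).  Segregation, de novo, and
functional-assay criteria have no inputs here and are excluded.  All
cutoffs live in `data/acmg.cfg`: allele-frequency bounds default to
PM2 < 1e-4, BS1 > 0.01, BA1 > 0.05 (guideline-cited conventions), the
predictor consensus fraction defaults to 0.75 of available predictors, and
per-predictor deleterious/benign score cutoffs are listed per tool-like
score name.  Config validation rejects cutoffs outside [0, 1] and any
ordering with the rare cutoff at or above the common one.

Combining follows the published rule table exactly (the test suite
enumerates all 2^11 subsets against an independently encoded copy).  Any
co-occurrence of pathogenic-side and benign-side triggers yields VUS, the
guideline's treatment of contradictory evidence; this keeps the combiner
monotone: adding pathogenic evidence never moves a label toward benign.
The default prioritization sorts pathogenic > likely pathogenic > VUS >
likely benign > benign, stable, with genomic (chrom, pos) tie-breaks;
predictor-score sorts place absent scores last.

## Protein structural context

**ASA.**  Shrake–Rupley with a Fibonacci (golden-spiral) point lattice,
default probe 1.4 Å and 960 points per atom; a point on the
solvent-expanded sphere is accessible iff it lies outside every other
atom's expanded sphere, and residue ASA sums its atoms.  Van der Waals
radii come from a fixed packaged element table (C 1.70, N 1.55, O 1.52,
S 1.80 Å) for reproducibility across PDB dialects.  Binary point counting
converges roughly as n^(−1/2): per-residue quadrature error at the 960-point
default is about 2% on the helix fixture, and doubling from a 3840-point
base changes per-residue values by under 1%, which is how the convergence
property is checked.

**RSA.**  ASA divided by the residue type's theoretical maximum (Tien et
al. 2013 table, shipped as an editable TSV), clamped to [0, 1].  Which
MaxASA scale to use and whether to clamp are genuinely open choices; both
are configuration here.  Protein-mean-RSA comparisons use the unweighted
mean over residues with computed ASA.

**Cα distances** are plain Euclidean distances between Cα coordinates;
residues lacking a Cα are reported absent rather than imputed.

**Secondary structure** is a 3-state (H/E/C) Kabsch–Sander
re-implementation, not 8-state DSSP parity.  The amide hydrogen is placed
on the backbone N along the bisector of the N→C(prev) and N→O(prev)
directions at 1.01 Å (prolines and chain starts/breaks donate nothing);
the electrostatic energy 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)
kcal/mol declares a bond below −0.5 kcal/mol.  Helix needs two consecutive
i→i+4 bonds (marking i+1…i+4); strand marks residues in parallel or
antiparallel bridge patterns; everything else is coil, including residues
with missing backbone atoms (warned, never fatal).

**Bridges.**  Disulfide candidates require the alternate residue to be
cysteine and a partner Sγ (or Cβ proxy when Sγ is absent, since the
wild-type structure does not carry the mutant side chain) within 2.5 Å;
salt-bridge candidates require opposite charges with terminal side-chain
atoms within 4.0 Å.  Both cutoffs are configurable; histidine is counted
positively charged for bridge purposes, a deliberate simplification at
pH 7.  Bridges supported by the reference residue are reported as lost.

**Context summary rule.**  The mutated site is tagged
"pathogenic-leaning" when it sits in a domain, is buried (RSA below the
protein mean), and carries a high predictor score (≥ 0.6);
"benign-leaning" when it is an exposed coil residue outside any domain
with a low score (≤ 0.4); otherwise "indeterminate".  This is a heuristic
reading aid, not a classifier.

## Synthetic fixtures

The generators produce everything the tests and the acceptance script
consume, deterministically under a seed.

* **Structures** are idealized poly-glycine backbones built by
  internal-coordinate chain extension (NeRF) with canonical bond geometry
  (helix φ = −57°, ψ = −47°; strand φ = −139°, ψ = +135°; ω = 180°;
  consecutive Cα–Cα ≈ 3.8 Å).  The antiparallel strand pair registers a
  C2-rotated copy of one strand against the canonical hydrogen-bond
  registry by deterministic rigid-body optimization; the hairpin closes
  two strands with a two-residue type II' turn, producing the
  sequence-far/space-close neighbor geometry; the cluster grows residues
  outward from a center on a sphere-spread spiral (prefix-stable in
  length) and exists to exercise burial monotonicity.  These fixtures have
  no side chains, no solvent, and perfect geometry — passing tests on them
  validates the geometry code, not behavior on noisy experimental
  structures.
* **The toy knowledge base** emulates the record shapes of three public
  evidence sources, not their content: a few dozen randomized rows around
  guaranteed cases (a cross-source duplicate, a substitutes record, all
  five biomarker-spec kinds for one gene, a tier-A sensitive gene-level
  record, an unmapped evidence code).  Real knowledge bases are far larger
  and messier; fixture results say nothing about clinical coverage.
* **Annotation tables** emulate dbNSFP/ClinVar-like fields per variant,
  with one clearly pathogenic and one clearly benign bundle guaranteed,
  plus protein-resolution columns standing in for an external
  genomic-to-protein conversion service.

## Problem sizes

The test suite and acceptance script run on deliberately small inputs —
20-residue backbones, 480–7680 quadrature points, 200-record knowledge
bases, a 3-record VCF, exhaustive 2^11 criterion enumeration — chosen so
every check recomputes from scratch in seconds while still exercising each
code path at full strength.

## Known limitations

Transcript-to-genome projection beyond the toy annotations, LiftOver
between assemblies, genome-FASTA allele verification, mmCIF input,
8-state secondary structure, mutant-structure prediction, and binding-site
prediction are out of scope; binding-site probabilities are inputs read
from a table.  The ACMG subset covers annotation-derived criteria only.
The fuzzy cancer-type threshold, tier mapping cells, predictor cutoffs,
and bridge cutoffs are documented defaults meant to be edited, not
empirical findings.
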