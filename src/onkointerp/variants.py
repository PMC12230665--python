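"""Variant parsing, validation, file I/O, and gene-fusion frame analysis.

Variants are accepted at three nomenclature levels:

* DNA level, HGVS ``g.`` notation: ``chr12:g.25245350C>T``
* transcript level, HGVS ``c.`` notation: ``NM_004985.5:c.35G>A``
* protein level: ``KRAS:p.G12D``, the knowledge-base shorthand
  ``KRAS G12D``, and three-letter forms ``p.Gly12Asp``

Genomic and coding-sequence positions are 1-based throughout, matching VCF
and HGVS conventions.  Chromosome labels are stored without the ``chr``
prefix; the reference genome is carried as metadata (default ``hg38``) and
never validated against a sequence.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import FormatError, ValidationError, VariantParseError

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*")

# three-letter -> one-letter, including the HGVS stop spelling
AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Glu": "E", "Gln": "Q", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}


class Level(str, Enum):
    DNA = "DNA"
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"


class VariantType(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    INDEL = "indel"
    FUSION = "fusion"
    GENE_ONLY = "gene_only"


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    UNDETERMINED = "undetermined"


@dataclass
class ParsedVariant:
    """One variant at one nomenclature level.

    The fields of the declared ``level`` must be populated; fields of other
    levels may additionally be populated when the source supplies them
    (e.g. a MAF row carries both genomic coordinates and a protein change).
    """

    level: Level
    chrom: str | None = None
    pos: int | None = None
    end_pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    transcript_id: str | None = None
    cds_pos: int | None = None
    gene: str | None = None
    ref_aa: str | None = None
    aa_pos: int | None = None
    alt_aa: str | None = None
    variant_type: VariantType | None = None
    genome_build: str = "hg38"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.level == Level.DNA:
            if self.chrom is None or self.pos is None:
                raise ValidationError("DNA-level variant requires chrom and pos")
            if self.pos < 1:
                raise ValidationError(f"genomic position must be >= 1, got {self.pos}")
        elif self.level == Level.TRANSCRIPT:
            if self.transcript_id is None or self.cds_pos is None:
                raise ValidationError(
                    "transcript-level variant requires transcript_id and cds_pos"
                )
            if self.cds_pos < 1:
                raise ValidationError(f"CDS position must be >= 1, got {self.cds_pos}")
        elif self.level == Level.PROTEIN:
            if self.gene is None:
                raise ValidationError("protein-level variant requires a gene symbol")
        for aa in (self.ref_aa, self.alt_aa):
            if aa is not None and aa not in AA_ALPHABET:
                raise ValidationError(f"not a one-letter amino acid: {aa!r}")
        if self.aa_pos is not None and self.aa_pos < 1:
            raise ValidationError(f"residue index must be >= 1, got {self.aa_pos}")
        if self.variant_type == VariantType.SNV:
            if self.level in (Level.DNA, Level.TRANSCRIPT):
                if not self.ref or not self.alt:
                    raise ValidationError("SNV requires non-empty ref and alt alleles")
                if self.ref == self.alt:
                    raise ValidationError("SNV requires ref != alt")
        if self.variant_type == VariantType.INSERTION and not (self.alt or self.alt_aa):
            raise ValidationError("insertion requires inserted bases")

    # -- canonical string ------------------------------------------------
    def to_query(self) -> str:
        """Canonical query-string form; ``parse_query`` round-trips it."""
        if self.level == Level.DNA:
            return f"chr{self.chrom}:g.{self._dna_change()}"
        if self.level == Level.TRANSCRIPT:
            return f"{self.transcript_id}:c.{self._dna_change(cds=True)}"
        if self.ref_aa is None:
            return str(self.gene)
        return f"{self.gene}:p.{self.ref_aa}{self.aa_pos}{self.alt_aa}"

    def _dna_change(self, cds: bool = False) -> str:
        pos = self.cds_pos if cds else self.pos
        if self.variant_type == VariantType.SNV:
            return f"{pos}{self.ref}>{self.alt}"
        if self.variant_type == VariantType.INSERTION:
            return f"{pos}_{self.end_pos}ins{self.alt}"
        if self.variant_type == VariantType.DELETION:
            span = f"{pos}" if self.end_pos in (None, pos) else f"{pos}_{self.end_pos}"
            return f"{span}del{self.ref or ''}"
        span = f"{pos}" if self.end_pos in (None, pos) else f"{pos}_{self.end_pos}"
        return f"{span}delins{self.alt}"

    def key(self) -> str:
        """Stable identifier used to join per-variant annotation tables."""
        if self.level == Level.DNA:
            return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
        if self.level == Level.TRANSCRIPT:
            return f"{self.transcript_id}:{self.cds_pos}:{self.ref}:{self.alt}"
        if self.ref_aa is None:
            return str(self.gene)
        return f"{self.gene}:{self.ref_aa}{self.aa_pos}{self.alt_aa}"


# ---------------------------------------------------------------------------
# query parsing


_DNA_RE = re.compile(r"^(?:chr)?([0-9]{1,2}|[XYM]|MT):g\.(.+)$", re.IGNORECASE)
_TX_RE = re.compile(r"^((?:[A-Z]{2}_\d+|ENST\d+)(?:\.\d+)?):c\.(.+)$")
_PROT_RE = re.compile(
    r"^([A-Za-z][A-Za-z0-9-]*)[ :]\s*(?:p\.)?\(?"
    r"([A-Za-z*]{1,3})(\d+)([A-Za-z*]{1,3})\)?$"
)
_GENE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9-]*$")

_SNV_RE = re.compile(r"^(\d+)([ACGTN])>([ACGTN])$", re.IGNORECASE)
_INS_RE = re.compile(r"^(\d+)_(\d+)ins([ACGTN]+)$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGTN]*)$", re.IGNORECASE)
_DELINS_RE = re.compile(r"^(\d+)(?:_(\d+))?delins([ACGTN]+)$", re.IGNORECASE)
_DUP_RE = re.compile(r"^(\d+)(?:_(\d+))?dup([ACGTN]*)$", re.IGNORECASE)


def _normalize_aa(token: str) -> str:
    """One- or three-letter amino-acid token -> one-letter code."""
    if len(token) == 1:
        aa = token.upper()
        if aa == "X":
            aa = "*"
        if aa not in AA_ALPHABET:
            raise VariantParseError(f"unknown amino acid {token!r}", token=token)
        return aa
    norm = token[0].upper() + token[1:].lower()
    if norm not in AA_3TO1:
        raise VariantParseError(f"unknown amino acid {token!r}", token=token)
    return AA_3TO1[norm]


def _parse_change(change: str) -> dict:
    """HGVS sequence-change token -> ParsedVariant field dict (pos-keyed)."""
    if m := _DELINS_RE.match(change):
        return dict(pos=int(m[1]), end_pos=int(m[2] or m[1]), ref=None,
                    alt=m[3].upper(), variant_type=VariantType.INDEL)
    if m := _SNV_RE.match(change):
        return dict(pos=int(m[1]), ref=m[2].upper(), alt=m[3].upper(),
                    variant_type=VariantType.SNV)
    if m := _INS_RE.match(change):
        return dict(pos=int(m[1]), end_pos=int(m[2]), ref="", alt=m[3].upper(),
                    variant_type=VariantType.INSERTION)
    if m := _DEL_RE.match(change):
        return dict(pos=int(m[1]), end_pos=int(m[2] or m[1]),
                    ref=m[3].upper() or None, alt="",
                    variant_type=VariantType.DELETION)
    if m := _DUP_RE.match(change):
        return dict(pos=int(m[1]), end_pos=int(m[2] or m[1]), ref="",
                    alt=m[3].upper() or None, variant_type=VariantType.INSERTION)
    raise VariantParseError(
        f"cannot parse sequence change {change!r} (expected e.g. 123A>G, "
        "10_11insAGG, 100_102del)", token=change)


def parse_query(text: str) -> ParsedVariant:
    """Parse a variant query string at DNA, transcript, or protein level.

    The nomenclature level is detected from syntax (``g.`` / ``c.`` markers,
    ``GENE:p.`` or ``GENE AA###AA`` shorthand, or a bare gene symbol).

    Raises
    ------
    VariantParseError
        If the string matches no known syntax; ``token`` names the first
        offending token.
    """
    if not text or not text.strip():
        raise VariantParseError("empty query", token="")
    text = text.strip()

    if m := _DNA_RE.match(text):
        chrom = m[1].upper() if m[1].upper() in {"X", "Y", "M", "MT"} else m[1]
        fields = _parse_change(m[2])
        return ParsedVariant(level=Level.DNA, chrom=chrom, **fields)
    if ":g." in text:
        raise VariantParseError(
            f"unrecognized chromosome token in {text!r}",
            token=text.split(":g.")[0])

    if m := _TX_RE.match(text):
        fields = _parse_change(m[2])
        fields["cds_pos"] = fields.pop("pos")  # c. positions are CDS-relative
        return ParsedVariant(level=Level.TRANSCRIPT, transcript_id=m[1], **fields)
    if ":c." in text:
        raise VariantParseError(
            f"unrecognized transcript accession in {text!r}",
            token=text.split(":c.")[0])

    if m := _PROT_RE.match(text):
        gene = m[1].upper()
        ref_aa = _normalize_aa(m[2])
        alt_aa = _normalize_aa(m[4])
        return ParsedVariant(
            level=Level.PROTEIN, gene=gene, ref_aa=ref_aa, aa_pos=int(m[3]),
            alt_aa=alt_aa,
            variant_type=VariantType.SNV if ref_aa != alt_aa else VariantType.SNV,
        )

    if _GENE_RE.match(text):
        return ParsedVariant(level=Level.PROTEIN, gene=text.upper(),
                             variant_type=VariantType.GENE_ONLY)

    raise VariantParseError(f"unparseable query {text!r}",
                            token=text.split()[0] if text.split() else text)


def recognize_variant_type(v: ParsedVariant) -> VariantType:
    """Re-derive the variant type from the populated allele fields.

    SNV iff both alleles are single bases (or a single residue exchange at
    protein level); insertion/deletion from allele-length asymmetry; falls
    back to indel; gene-only when only a symbol is present.
    """
    if v.level == Level.PROTEIN and v.ref_aa is None:
        return VariantType.GENE_ONLY
    if v.level == Level.PROTEIN:
        return VariantType.SNV
    ref, alt = v.ref or "", v.alt or ""
    if len(ref) == 1 and len(alt) == 1 and ref != alt:
        return VariantType.SNV
    if ref == "" and alt:
        return VariantType.INSERTION
    if alt == "" or (ref and alt and len(ref) > len(alt) and ref.endswith(alt)):
        return VariantType.DELETION
    if ref and alt and len(alt) > len(ref) and alt.startswith(ref):
        return VariantType.INSERTION
    return VariantType.INDEL


# ---------------------------------------------------------------------------
# file I/O


@dataclass
class VariantCollection:
    """Variants read from a file plus pass-through header and skip counts."""

    variants: list[ParsedVariant]
    header: str = ""
    source_format: str = "list"
    skipped: int = 0

    def __iter__(self) -> Iterator[ParsedVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


MAF_REQUIRED = ["Hugo_Symbol", "Chromosome", "Start_Position",
                "Reference_Allele", "Tumor_Seq_Allele2"]


def read_variant_file(path: str | Path, format: str) -> VariantCollection:
    """Read a VCF, MAF, or plain-list file into parsed variants.

    VCF multi-allelic records are expanded to one variant per alternate
    allele.  Records failing validation are skipped and counted with a
    warning.  The VCF header is passed through for later export.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "maf":
        return _read_maf(path)
    if format == "list":
        return _read_list(path)
    raise FormatError(f"unknown format {format!r}; expected vcf, maf, or list")


def _read_vcf(path: Path) -> VariantCollection:
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"not a readable VCF: {path} ({exc})") from exc
    header = str(vf.header)
    variants: list[ParsedVariant] = []
    skipped = 0
    for rec in vf:
        for alt in rec.alts or ():
            if alt.startswith("<"):  # symbolic alleles carry no sequence
                skipped += 1
                continue
            try:
                ref, a = rec.ref, alt
                vtype = VariantType.SNV if len(ref) == 1 and len(a) == 1 else None
                v = ParsedVariant(
                    level=Level.DNA,
                    chrom=rec.chrom.removeprefix("chr"),
                    pos=rec.pos, ref=ref, alt=a, variant_type=vtype,
                    meta={"chrom_raw": rec.chrom, "vcf_id": rec.id or "."},
                )
                v.variant_type = recognize_variant_type(v)
                variants.append(v)
            except ValidationError as exc:
                skipped += 1
                logger.warning("skipping VCF record %s:%s: %s", rec.chrom, rec.pos, exc)
    if skipped:
        logger.warning("skipped %d VCF record(s)", skipped)
    return VariantCollection(variants, header=header, source_format="vcf",
                             skipped=skipped)


def _read_maf(path: Path) -> VariantCollection:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"MAF is missing mandatory column(s): {', '.join(missing)}")
    variants: list[ParsedVariant] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            v = ParsedVariant(
                level=Level.DNA,
                chrom=str(row["Chromosome"]).removeprefix("chr"),
                pos=int(row["Start_Position"]),
                ref=row["Reference_Allele"],
                alt=row["Tumor_Seq_Allele2"],
                gene=row["Hugo_Symbol"],
            )
            v.variant_type = recognize_variant_type(v)
            hgvsp = row.get("HGVSp_Short")
            if isinstance(hgvsp, str) and hgvsp.strip():
                try:
                    p = parse_query(f"{row['Hugo_Symbol']}:{hgvsp.strip()}")
                    v.ref_aa, v.aa_pos, v.alt_aa = p.ref_aa, p.aa_pos, p.alt_aa
                except VariantParseError:
                    logger.warning("unparseable HGVSp_Short %r", hgvsp)
            variants.append(v)
        except (ValidationError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping MAF row: %s", exc)
    if skipped:
        logger.warning("skipped %d MAF row(s)", skipped)
    return VariantCollection(variants, source_format="maf", skipped=skipped)


def _read_list(path: Path) -> VariantCollection:
    variants: list[ParsedVariant] = []
    skipped = 0
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            variants.append(parse_query(line))
        except VariantParseError as exc:
            skipped += 1
            logger.warning("skipping query %r: %s", line, exc)
    if skipped:
        logger.warning("skipped %d query line(s)", skipped)
    return VariantCollection(variants, source_format="list", skipped=skipped)


_BUILTIN_FIELDS = ["query", "level", "chrom", "pos", "ref", "alt",
                   "transcript_id", "cds_pos", "gene", "ref_aa", "aa_pos",
                   "alt_aa", "variant_type", "genome_build"]


def _variant_field(v: ParsedVariant, name: str) -> str:
    if name == "query":
        return v.to_query()
    val = getattr(v, name)
    if isinstance(val, Enum):
        return val.value
    return "" if val is None else str(val)


def write_variant_table(
    variants: Sequence[ParsedVariant],
    annotations: Sequence[dict] | None,
    selected_fields: Sequence[str],
    path: str | Path,
) -> None:
    """Export variants (plus per-variant annotation dicts) as RFC-4180 CSV.

    ``selected_fields`` become the columns, in the given order.  Unknown
    field names raise an error that lists the valid choices.
    """
    annotations = annotations or [{} for _ in variants]
    if not variants:  # header-only export
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerow(selected_fields)
        return
    available = set(_BUILTIN_FIELDS)
    for ann in annotations:
        available.update(ann)
    bad = [f for f in selected_fields if f not in available]
    if bad:
        raise ValidationError(
            f"unknown field(s) {', '.join(bad)}; valid fields: "
            f"{', '.join(sorted(available))}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(selected_fields)
        for v, ann in zip(variants, annotations):
            w.writerow([
                str(ann[f]) if f in ann else
                _variant_field(v, f) if f in _BUILTIN_FIELDS else ""
                for f in selected_fields
            ])


def write_vcf(collection: VariantCollection, path: str | Path) -> None:
    """Re-write DNA-level variants as VCF, preserving the read header.

    CHROM, POS, REF, ALT survive a read/write round trip byte-exactly for
    biallelic SNVs (multi-allelic records were expanded at read time).
    """
    lines = []
    header = collection.header.rstrip("\n")
    if not header:
        header = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    lines.append(header)
    for v in collection.variants:
        chrom = v.meta.get("chrom_raw", v.chrom)
        vid = v.meta.get("vcf_id", ".")
        lines.append(f"{chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# transcripts and gene fusions


@dataclass
class TranscriptAnnotation:
    """Exon/CDS layout of one transcript (1-based inclusive genomic intervals)."""

    transcript_id: str
    gene: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError("exons overlap")
        if not any(s <= self.cds_start <= e for s, e in self.exons) or \
           not any(s <= self.cds_end <= e for s, e in self.exons):
            raise ValidationError("CDS boundaries fall outside the exon union")

    def coding_positions(self) -> list[int]:
        """Genomic coordinates of coding bases, in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)
               if self.cds_start <= p <= self.cds_end]
        return pos if self.strand == "+" else pos[::-1]

    def exon_index_of(self, genomic_pos: int) -> int | None:
        """1-based exon number in transcript orientation, or None."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        for i, (s, e) in enumerate(order, start=1):
            if s <= genomic_pos <= e:
                return i
        return None

    def exon_of_residue(self, aa_pos: int) -> int | None:
        """Exon number containing the first base of residue ``aa_pos``'s codon."""
        coding = self.coding_positions()
        idx = (aa_pos - 1) * 3
        if idx >= len(coding):
            return None
        return self.exon_index_of(coding[idx])


@dataclass
class FusionEvent:
    """A gene fusion defined by two chromosomes and breakpoints.

    ``breakpoint_a`` is the last retained base of the 5' partner;
    ``breakpoint_b`` is the first retained base of the 3' partner.
    """

    chrom_a: str
    breakpoint_a: int
    chrom_b: str
    breakpoint_b: int
    gene_a: str | None = None
    gene_b: str | None = None
    frame_status: FrameStatus = FrameStatus.UNDETERMINED

    def __post_init__(self) -> None:
        if self.breakpoint_a < 1 or self.breakpoint_b < 1:
            raise ValidationError("breakpoints must be >= 1")


def fusion_in_frame(
    f: FusionEvent,
    annotation_a: TranscriptAnnotation,
    annotation_b: TranscriptAnnotation,
) -> FrameStatus:
    """Determine whether a fusion joins the two coding frames compatibly.

    The retained coding length of the 5' partner up to ``breakpoint_a``
    (mod 3) must equal the 3' partner's codon offset at ``breakpoint_b``
    for the downstream frame to be preserved.  Breakpoints in UTRs,
    introns, or outside the transcript yield ``undetermined``.
    """
    coding_a = annotation_a.coding_positions()
    coding_b = annotation_b.coding_positions()
    if f.breakpoint_a not in set(coding_a) or f.breakpoint_b not in set(coding_b):
        return FrameStatus.UNDETERMINED
    retained5 = coding_a.index(f.breakpoint_a) + 1
    offset3 = coding_b.index(f.breakpoint_b)
    status = (FrameStatus.IN_FRAME if retained5 % 3 == offset3 % 3
              else FrameStatus.OUT_OF_FRAME)
    f.frame_status = status
    f.gene_a = f.gene_a or annotation_a.gene
    f.gene_b = f.gene_b or annotation_b.gene
    return status
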