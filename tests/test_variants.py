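"""Variant parsing, file I/O, and fusion frame determination."""

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onkointerp.errors import FormatError, ValidationError, VariantParseError
from onkointerp.variants import (FrameStatus, FusionEvent, Level, ParsedVariant,
                                 TranscriptAnnotation, VariantType,
                                 fusion_in_frame, parse_query,
                                 read_variant_file, recognize_variant_type,
                                 write_variant_table, write_vcf)


class TestParseQuery:
    @pytest.mark.parametrize("text,level,fields", [
        ("chr12:g.25245350C>T", Level.DNA,
         dict(chrom="12", pos=25245350, ref="C", alt="T")),
        ("NM_004985.5:c.35G>A", Level.TRANSCRIPT,
         dict(transcript_id="NM_004985.5", cds_pos=35, ref="G", alt="A")),
        ("KRAS:p.G12D", Level.PROTEIN,
         dict(gene="KRAS", ref_aa="G", aa_pos=12, alt_aa="D")),
        ("KRAS G12D", Level.PROTEIN,
         dict(gene="KRAS", ref_aa="G", aa_pos=12, alt_aa="D")),
        ("KRAS:p.Gly12Asp", Level.PROTEIN,
         dict(gene="KRAS", ref_aa="G", aa_pos=12, alt_aa="D")),
        ("KRAS:p.(G12D)", Level.PROTEIN,
         dict(gene="KRAS", ref_aa="G", aa_pos=12, alt_aa="D")),
        ("12:g.25245350C>T", Level.DNA, dict(chrom="12", pos=25245350)),
        ("chrX:g.1000A>G", Level.DNA, dict(chrom="X", pos=1000)),
    ])
    def test_levels_and_fields(self, text, level, fields):
        v = parse_query(text)
        assert v.level == level
        for name, expected in fields.items():
            assert getattr(v, name) == expected

    def test_gene_only(self):
        v = parse_query("BRAF")
        assert v.level == Level.PROTEIN
        assert v.gene == "BRAF"
        assert v.variant_type == VariantType.GENE_ONLY

    @pytest.mark.parametrize("text", [
        "chr12:g.C>T",          # missing position
        "", "   ",
        "chr12:g.123",          # no allele change
        "NM_1:c.bogus",
    ])
    def test_parse_errors_name_token(self, text):
        with pytest.raises(VariantParseError) as err:
            parse_query(text)
        assert isinstance(err.value.token, str)

    def test_stop_codon_accepted(self):
        v = parse_query("TP53:p.R196*")
        assert v.alt_aa == "*"

    @pytest.mark.parametrize("text,vtype", [
        ("NM_1:c.10_11insAGG", VariantType.INSERTION),
        ("chr1:g.100_102del", VariantType.DELETION),
        ("chr1:g.100delinsTT", VariantType.INDEL),
    ])
    def test_indel_syntax(self, text, vtype):
        assert parse_query(text).variant_type == vtype


class TestRecognizeVariantType:
    def test_snv(self):
        v = parse_query("chr1:g.5C>T")
        assert recognize_variant_type(v) == VariantType.SNV

    def test_insertion_keyword(self):
        v = parse_query("NM_1:c.10_11insAGG")
        assert recognize_variant_type(v) == VariantType.INSERTION

    def test_gene_only(self):
        assert recognize_variant_type(parse_query("BRAF")) == VariantType.GENE_ONLY


@settings(max_examples=60, deadline=None)
@given(chrom=st.sampled_from(["1", "12", "X"]),
       pos=st.integers(min_value=1, max_value=10**8),
       ref=st.sampled_from("ACGT"), alt=st.sampled_from("ACGT"))
def test_parse_format_roundtrip_dna(chrom, pos, ref, alt):
    """parse -> canonical string -> parse is identity for DNA SNVs."""
    if ref == alt:
        return
    v = parse_query(f"chr{chrom}:g.{pos}{ref}>{alt}")
    again = parse_query(v.to_query())
    assert (again.chrom, again.pos, again.ref, again.alt) == (chrom, pos, ref, alt)


@settings(max_examples=60, deadline=None)
@given(gene=st.sampled_from(["KRAS", "BRAF", "TP53"]),
       ref=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
       pos=st.integers(min_value=1, max_value=5000),
       alt=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
def test_parse_format_roundtrip_protein(gene, ref, pos, alt):
    v = parse_query(f"{gene}:p.{ref}{pos}{alt}")
    again = parse_query(v.to_query())
    assert (again.gene, again.ref_aa, again.aa_pos, again.alt_aa) == \
        (gene, ref, pos, alt)


class TestVariantFiles:
    def test_vcf_read(self, fixture_dir):
        coll = read_variant_file(fixture_dir / "variants.vcf", "vcf")
        assert len(coll) == 3
        assert all(v.level == Level.DNA and v.pos >= 1 for v in coll)
        assert coll.variants[0].chrom == "12"  # "chr" stripped internally

    def test_vcf_multiallelic_expansion(self, tmp_path):
        p = tmp_path / "ma.vcf"
        p.write_text("##fileformat=VCFv4.2\n##contig=<ID=1>\n"
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                     "1\t100\t.\tG\tA,T\t.\t.\t.\n")
        coll = read_variant_file(p, "vcf")
        assert [v.alt for v in coll] == ["A", "T"]

    def test_vcf_roundtrip_preserves_core_fields(self, fixture_dir, tmp_path):
        coll = read_variant_file(fixture_dir / "variants.vcf", "vcf")
        out = tmp_path / "rt.vcf"
        write_vcf(coll, out)
        original = [ln.split("\t")[:5] for ln in
                    (fixture_dir / "variants.vcf").read_text().splitlines()
                    if not ln.startswith("#")]
        rewritten = [ln.split("\t")[:5] for ln in out.read_text().splitlines()
                     if not ln.startswith("#")]
        assert rewritten == original

    def test_maf_populates_protein_fields(self, fixture_dir):
        coll = read_variant_file(fixture_dir / "variants.maf", "maf")
        kras = coll.variants[0]
        assert (kras.gene, kras.ref_aa, kras.aa_pos, kras.alt_aa) == \
            ("KRAS", "G", 12, "D")
        assert kras.level == Level.DNA  # genomic fields stay primary

    def test_maf_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text("Hugo_Symbol\tChromosome\nKRAS\t12\n")
        with pytest.raises(FormatError, match="Start_Position"):
            read_variant_file(p, "maf")

    def test_plain_list(self, tmp_path):
        p = tmp_path / "queries.txt"
        p.write_text("KRAS:p.G12D\nnot a variant ( \nBRAF\n")
        coll = read_variant_file(p, "list")
        assert len(coll) == 2 and coll.skipped == 1


class TestVariantTable:
    def test_selected_fields_in_order(self, tmp_path):
        vs = [parse_query("KRAS:p.G12D"), parse_query("BRAF:p.V600E")]
        out = tmp_path / "t.csv"
        write_variant_table(vs, None, ["gene", "aa_pos"], out)
        rows = list(csv.reader(out.open()))
        assert rows == [["gene", "aa_pos"], ["KRAS", "12"], ["BRAF", "600"]]

    def test_empty_list_writes_header_only(self, tmp_path):
        out = tmp_path / "t.csv"
        write_variant_table([], None, ["gene"], out)
        assert out.read_text().strip() == "gene"

    def test_embedded_comma_survives_roundtrip(self, tmp_path):
        v = parse_query("KRAS:p.G12D")
        out = tmp_path / "t.csv"
        write_variant_table([v], [{"note": 'hello, "world"'}],
                            ["gene", "note"], out)
        rows = list(csv.reader(out.open()))
        assert rows[1] == ["KRAS", 'hello, "world"']

    def test_unknown_field_lists_valid(self, tmp_path):
        with pytest.raises(ValidationError, match="valid fields"):
            write_variant_table([parse_query("BRAF")], None,
                                ["nope"], tmp_path / "t.csv")


# ---------------------------------------------------------------------------
# gene fusions


def _toy_pair():
    ann_a = TranscriptAnnotation("A.1", "TOYA", "+",
                                 [(100, 260), (340, 560)], 121, 540)
    ann_b = TranscriptAnnotation("B.1", "TOYB", "-",
                                 [(1000, 1100), (1200, 1320)], 1050, 1260)
    return ann_a, ann_b


def _oracle_frame(ann_a, ann_b, bp_a, bp_b):
    """Brute-force codon walker over explicit per-base coding sequences.

    Assigns each coding base its codon phase by walking the transcript in
    5'->3' order; the fusion preserves frame iff the phase after the
    retained 5' segment equals the 3' base's phase in its own transcript.
    """
    coding_a = ann_a.coding_positions()
    coding_b = ann_b.coding_positions()
    if bp_a not in coding_a or bp_b not in coding_b:
        return FrameStatus.UNDETERMINED
    phase_after_5p = 0
    for pos in coding_a:
        phase_after_5p = (phase_after_5p + 1) % 3
        if pos == bp_a:
            break
    phase_of_3p = coding_b.index(bp_b) % 3
    return (FrameStatus.IN_FRAME if phase_after_5p == phase_of_3p
            else FrameStatus.OUT_OF_FRAME)


class TestFusionFrame:
    def test_codon_boundary_in_frame(self):
        ann_a, ann_b = _toy_pair()
        # 300 retained coding nt in the 5' partner: coding base #300
        bp_a = ann_a.coding_positions()[299]
        bp_b = ann_b.coding_positions()[0]  # codon boundary of the 3' gene
        f = FusionEvent("1", bp_a, "2", bp_b)
        assert fusion_in_frame(f, ann_a, ann_b) == FrameStatus.IN_FRAME

    def test_one_base_shift_out_of_frame(self):
        ann_a, ann_b = _toy_pair()
        bp_a = ann_a.coding_positions()[300]  # 301 retained nt
        bp_b = ann_b.coding_positions()[0]
        f = FusionEvent("1", bp_a, "2", bp_b)
        assert fusion_in_frame(f, ann_a, ann_b) == FrameStatus.OUT_OF_FRAME

    def test_utr_breakpoint_undetermined(self):
        ann_a, ann_b = _toy_pair()
        f = FusionEvent("1", 111, "2", ann_b.coding_positions()[0])
        assert fusion_in_frame(f, ann_a, ann_b) == FrameStatus.UNDETERMINED

    def test_exhaustive_sweep_matches_codon_walker(self):
        """Every breakpoint pair across the toy 2-exon gene pair agrees with
        the brute-force codon-continuity oracle."""
        ann_a, ann_b = _toy_pair()
        pos_a = list(range(95, 465, 7)) + [121, 420]
        pos_b = list(range(995, 1325, 7)) + [1050, 1260]
        for bp_a in pos_a:
            for bp_b in pos_b:
                f = FusionEvent("1", bp_a, "2", bp_b)
                assert fusion_in_frame(f, ann_a, ann_b) == \
                    _oracle_frame(ann_a, ann_b, bp_a, bp_b), (bp_a, bp_b)
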