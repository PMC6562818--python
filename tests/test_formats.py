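"""FASTA/GFF3/pileup/VCF readers and writers, and variant-key normalization."""

import random

import pytest

from poolvar.caller import VariantCall
from poolvar.config import GenomicInterval
from poolvar.formats import (
    FormatError,
    PileupParseError,
    VariantKey,
    left_align_key,
    parse_pileup_line,
    read_bed,
    read_fasta,
    read_gff3,
    read_vcf,
    var_type,
    write_bed,
    write_vcf,
)

from _oracles import random_pileup_line


class TestFasta:
    def test_basic_and_header_truncation(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr16\nACGT\n>a x\nacgt\n")
        assert read_fasta(p) == {"chr16": "ACGT", "a": "ACGT"}

    def test_duplicate_id_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_record_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\n\n>b\nACGT\n")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(p)


GFF_PLUS = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t{strand}\t.\tID=g1
chr1\tsrc\tmRNA\t101\t400\t.\t{strand}\t.\tID=t1;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t{strand}\t.\tID=e1;Parent=t1
chr1\tsrc\texon\t301\t400\t.\t{strand}\t.\tID=e2;Parent=t1
chr1\tsrc\tCDS\t151\t200\t.\t{strand}\t0\tID=c1;Parent=t1
chr1\tsrc\tCDS\t301\t350\t.\t{strand}\t0\tID=c2;Parent=t1
"""


class TestGff3:
    def test_plus_strand_utr_projection(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_PLUS.format(strand="+"))
        (m,) = read_gff3(p)
        assert m.tss == 101
        assert [(u.start, u.end) for u in m.utr5] == [(101, 150)]
        assert [(u.start, u.end) for u in m.utr3] == [(351, 400)]

    def test_minus_strand_mirror(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_PLUS.format(strand="-"))
        (m,) = read_gff3(p)
        assert m.tss == 400
        assert [(u.start, u.end) for u in m.utr5] == [(351, 400)]
        assert [(u.start, u.end) for u in m.utr3] == [(101, 150)]

    def test_cds_outside_exons_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tmRNA\t101\t200\t.\t+\t.\tID=t1\n"
            "chr1\ts\texon\t101\t200\t.\t+\t.\tID=e1;Parent=t1\n"
            "chr1\ts\tCDS\t90\t95\t.\t+\t0\tID=c1;Parent=t1\n"
        )
        with pytest.raises(FormatError, match="outside"):
            read_gff3(p)

    def test_orphan_parent_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tmRNA\t101\t200\t.\t+\t.\tID=t1\n"
            "chr1\ts\texon\t101\t200\t.\t+\t.\tID=e1;Parent=ghost\n"
        )
        with pytest.raises(FormatError, match="ghost"):
            read_gff3(p)


class TestPileupParser:
    def test_all_match_line(self):
        site = parse_pileup_line("chr16\t74016\tA\t6\t.,.,.,\tIIIIII", "P1")
        assert site.depth == 6 and site.base_counts == {"A": 6}

    def test_deletion_allele(self):
        # 9 reference matches; the '-9CCACTGCCA' spec rides on the 5th one
        site = parse_pileup_line(
            "chr16\t74015\tG\t9\t.....-9CCACTGCCA....\tIIIIIIIII", "P1"
        )
        assert site.base_counts == {"G": 9, "-CCACTGCCA": 1}

    def test_case_folding_mismatches(self):
        site = parse_pileup_line("chr11\t4464202\tG\t8\t..AAAA,,\tIIIIIIII", "P1")
        assert site.base_counts == {"G": 4, "A": 4}

    def test_caret_skips_quality_char_and_star_not_counted(self):
        site = parse_pileup_line("c\t1\tT\t3\t^I.*,\tIII", "P1")
        assert site.base_counts == {"T": 2}

    def test_truncated_indel_is_parse_error(self):
        with pytest.raises(PileupParseError, match="column"):
            parse_pileup_line("c\t1\tT\t2\t.+5AC\tII", "P1")

    def test_depth_mismatch_warns_not_errors(self):
        with pytest.warns(UserWarning, match="depth"):
            site = parse_pileup_line("c\t1\tT\t9\t...\tIII", "P1")
        assert site.depth == 9

    def test_parser_matches_generator_tally_on_random_grammar_strings(self):
        rng = random.Random(20240917)
        for _ in range(1200):
            line, tally, observed = random_pileup_line(rng)
            site = parse_pileup_line(line, "P")
            assert site.base_counts == tally, line


class TestVcfRoundTrip:
    def _call(self, key, zyg="pool-heterozygous", depth=30, ac=12, p=1.2e-60):
        return VariantCall(
            key=key, var_type=var_type(key), pool_id="BY-H", depth=depth,
            alt_count=ac, zygosity_class=zyg, p_value=p,
        )

    def test_snp_and_indel_representation(self, tmp_path):
        calls = [
            self._call(VariantKey("Chr16", 74015, "G" + "CCACTGCCA", "G"), depth=20, ac=18,
                       zyg="pool-homozygous"),
            self._call(VariantKey("Chr16", 213135, "C", "G")),
        ]
        p = tmp_path / "x.vcf"
        write_vcf(calls, p)
        text = p.read_text()
        assert "GCCACTGCCA\tG" in text  # anchor + 9 deleted bases vs anchor
        assert "213135\t.\tC\tG" in text

    def test_roundtrip_identity_including_tiny_pvalues(self, tmp_path):
        calls = sorted(
            [
                self._call(VariantKey("c1", 10, "A", "T"), p=0.01**30),
                self._call(VariantKey("c1", 55, "T", "T" + "AGG")),
                self._call(VariantKey("c2", 7, "GAT", "G"), zyg="pool-homozygous", p=3.5e-200),
            ],
            key=lambda c: c.key,
        )
        p = tmp_path / "x.vcf"
        write_vcf(calls, p)
        assert read_vcf(p) == calls

    def test_unsorted_input_rejected(self, tmp_path):
        calls = [
            self._call(VariantKey("c1", 55, "A", "T")),
            self._call(VariantKey("c1", 10, "A", "T")),
        ]
        with pytest.raises(FormatError, match="sorted"):
            write_vcf(calls, tmp_path / "x.vcf")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tBY-H\n"
            "c1\tnotanumber\t.\tA\tT\t.\tPASS\tDP=9;AC=3;PV=0.1\tGT\t0/1\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            read_vcf(p)


class TestKeyNormalization:
    def test_left_shift_in_homopolymer(self):
        #        123456789
        seq = "GGAAAAACTT"
        # deleting one A anchored late shifts to the leftmost anchor G at pos 2
        key = left_align_key(VariantKey("c", 6, "AA", "A"), seq)
        assert key == VariantKey("c", 2, "GA", "G")

    def test_insertion_shift(self):
        seq = "GGAAAAACTT"
        key = left_align_key(VariantKey("c", 7, "A", "AA"), seq)
        assert key == VariantKey("c", 2, "G", "GA")

    def test_snp_unchanged(self):
        assert left_align_key(VariantKey("c", 3, "A", "T"), "GGAAA") == VariantKey("c", 3, "A", "T")

    def test_var_type(self):
        assert var_type(VariantKey("c", 1, "A", "T")) == "SNP"
        assert var_type(VariantKey("c", 1, "A", "AT")) == "INS"
        assert var_type(VariantKey("c", 1, "AT", "A")) == "DEL"
        with pytest.raises(ValueError):
            var_type(VariantKey("c", 1, "AT", "GC"))


def test_bed_roundtrip_converts_coordinates(tmp_path):
    regions = [GenomicInterval("11", 4_412_041, 5_661_311)]
    p = tmp_path / "r.bed"
    write_bed(regions, p)
    assert p.read_text() == "11\t4412040\t5661311\n"
    assert read_bed(p) == regions
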