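"""Annotator: promoter windows, component precedence, codon effects."""

import random

import pytest

from poolvar.annotate import (
    GeneIndex,
    annotate_key,
    cds_effect,
    indel_class,
    locate,
    promoter_interval,
)
from poolvar.config import GeneModel, GenomicInterval
from poolvar.formats import VariantKey

from _oracles import mirror_gene, random_plus_gene, revcomp

BASES = "ACGT"


class TestPromoterInterval:
    def _gene(self, strand, lo, hi):
        return GeneModel(
            "g", "c", strand, (GenomicInterval("c", lo, hi, strand),),
        )

    def test_plus_strand(self):
        prom = promoter_interval(self._gene("+", 5000, 6000), 2000)
        assert (prom.start, prom.end) == (3000, 4999)

    def test_minus_strand_mirror(self):
        prom = promoter_interval(self._gene("-", 4000, 5000), 2000)
        assert (prom.start, prom.end) == (5001, 7000)

    def test_clipped_at_chromosome_start(self):
        prom = promoter_interval(self._gene("+", 100, 900), 2000)
        assert (prom.start, prom.end) == (1, 99)

    def test_clipped_at_chromosome_end(self):
        prom = promoter_interval(self._gene("-", 100, 900), 2000, chrom_length=1500)
        assert (prom.start, prom.end) == (901, 1500)

    def test_gene_at_edge_has_no_promoter(self):
        assert promoter_interval(self._gene("+", 1, 900), 2000) is None


class TestLocate:
    def test_dual_gene_assignment_utr3_and_intron(self, overlap_models):
        # tap1_like 3'UTR is [4799, 5000]; bf1_like intron is [4101, 7199]
        index = GeneIndex(overlap_models, promoter_length=2000)
        key = VariantKey("chr16", 4850, "G" + "CCACTGCCA", "G")
        hits = dict(locate(key, index))
        assert hits == {"tap1_like": "utr3", "bf1_like": "intron"}

    def test_promoter_boundary_one_bp_upstream(self, plus_gene):
        index = GeneIndex([plus_gene], promoter_length=2000)
        hits = locate(VariantKey("chr1", 100, "A", "T"), index)
        assert hits == (("gplus", "promoter"),)

    def test_intergenic_far_from_everything(self, plus_gene):
        index = GeneIndex([plus_gene], promoter_length=2000)
        assert locate(VariantKey("chr1", 90_000, "A", "T"), index) == ()

    def test_unknown_chrom_is_empty_not_error(self, plus_gene):
        index = GeneIndex([plus_gene], promoter_length=2000)
        assert locate(VariantKey("chrZZ", 120, "A", "T"), index) == ()

    def test_precedence_cds_beats_utr_and_intron(self, plus_gene):
        index = GeneIndex([plus_gene], promoter_length=2000)
        # deletion footprint spanning utr5/CDS boundary reports CDS
        key = VariantKey("chr1", 148, "A" * 6, "A")
        assert dict(locate(key, index))["gplus"] == "CDS"


class TestCdsEffect:
    def _genome_with(self, cds_seq, gene):
        """Genome where the gene's CDS spells cds_seq (+ strand layout)."""
        seq = list("A" * 600)
        consumed = 0
        for seg in gene.cds_segments:
            for i in range(seg.length):
                seq[seg.start - 1 + i] = cds_seq[consumed + i]
            consumed += seg.length
        return {"chr1": "".join(seq)}

    def _gene(self):
        return GeneModel(
            "g", "chr1", "+",
            exons=(GenomicInterval("chr1", 101, 112, "+"),),
            cds_segments=(GenomicInterval("chr1", 101, 112, "+"),),
        )

    def test_wobble_synonymous(self):
        gene = self._gene()
        genome = self._genome_with("GGAGGAGGAGGA", gene)
        # third codon position GGA->GGG: Gly->Gly
        key = VariantKey("chr1", 103, "A", "G")
        assert cds_effect(key, gene, genome) == "synonymous"

    def test_first_position_nonsynonymous(self):
        gene = self._gene()
        genome = self._genome_with("AAAGGAGGAGGA", gene)
        # AAA->GAA: Lys->Glu
        key = VariantKey("chr1", 101, "A", "G")
        assert cds_effect(key, gene, genome) == "non-synonymous"

    def test_stop_gain_counts_nonsynonymous(self):
        gene = self._gene()
        genome = self._genome_with("TACGGAGGAGGA", gene)
        # TAC (Tyr) -> TAA (stop)
        key = VariantKey("chr1", 103, "C", "A")
        assert cds_effect(key, gene, genome) == "non-synonymous"

    def test_frame_violation_names_gene(self):
        gene = GeneModel(
            "gbad", "chr1", "+",
            exons=(GenomicInterval("chr1", 101, 110, "+"),),
            cds_segments=(GenomicInterval("chr1", 101, 110, "+"),),
        )
        with pytest.raises(ValueError, match="gbad"):
            cds_effect(VariantKey("chr1", 103, "A", "G"), gene, {"chr1": "A" * 200})

    def test_strand_mirror_invariance_on_random_models(self):
        """Annotating a CDS SNP on a '-' strand gene must equal annotating
        the reverse-complemented construct on the mirrored '+' gene."""
        rng = random.Random(2024)
        L = 3000
        for _ in range(100):
            gene = random_plus_gene(rng, L)
            seq = "".join(rng.choice(BASES) for _ in range(L))
            genome = {"chrM": seq}
            seg = gene.cds_segments[rng.randrange(len(gene.cds_segments))]
            pos = rng.randint(seg.start, seg.end)
            ref = seq[pos - 1]
            alt = rng.choice([b for b in BASES if b != ref])
            eff_plus = cds_effect(VariantKey("chrM", pos, ref, alt), gene, genome)

            mirror = mirror_gene(gene, L)
            genome_rc = {"chrM": revcomp(seq)}
            pos_m = L - pos + 1
            comp = dict(zip("ACGT", "TGCA"))
            eff_minus = cds_effect(
                VariantKey("chrM", pos_m, comp[ref], comp[alt]), mirror, genome_rc
            )
            assert eff_plus == eff_minus


class TestIndelClass:
    def test_nine_bp_deletion(self):
        key = VariantKey("Chr16", 74015, "G" + "CCACTGCCA", "G")
        assert indel_class(key) == "deletion"
        assert len(key.ref) - len(key.alt) == 9

    def test_single_base_insertion(self):
        assert indel_class(VariantKey("c", 5, "T", "TA")) == "insertion"

    def test_equal_length_is_contract_error(self):
        with pytest.raises(ValueError):
            indel_class(VariantKey("c", 5, "AT", "GC"))


class TestAnnotateKey:
    def test_component_precedence_is_a_function(self, overlap_models):
        """Exactly one component per (variant, gene) pair, even for a
        footprint spanning several components."""
        index = GeneIndex(overlap_models, promoter_length=2000)
        genome = {"chr16": "A" * 9000}
        for pos in range(1000, 8000, 37):
            rec = annotate_key(VariantKey("chr16", pos, "A", "T"), index, genome)
            genes = [g for g, _ in rec.hits]
            assert len(genes) == len(set(genes))

    def test_in_gene_requires_non_promoter_hit(self, plus_gene):
        index = GeneIndex([plus_gene], promoter_length=2000)
        rec = annotate_key(VariantKey("chr1", 50, "A", "T"), index, {"chr1": "A" * 500})
        assert rec.hits == (("gplus", "promoter"),)
        assert not rec.in_gene and not rec.in_mrna

    def test_indel_in_cds_keeps_noncoding_effect(self, plus_gene):
        genome = {"chr1": "A" * 500}
        index = GeneIndex([plus_gene], promoter_length=2000)
        rec = annotate_key(VariantKey("chr1", 160, "AAAA", "A"), index, genome)
        assert rec.effect == "non-coding"
        assert rec.indel_class == "deletion"
        assert dict(rec.hits)["gplus"] == "CDS"
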