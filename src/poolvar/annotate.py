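"""Variant annotation against gene models.

Each variant's reference footprint is intersected with every gene whose
body or proximal promoter it touches.  Per gene, the single most specific
component is reported with precedence CDS > UTR > intron > promoter; hits
for multiple genes are all kept, so a deletion sitting in one gene's 3'UTR
and another gene's intron is reported under both (the overlapping-gene
case on microchromosome 16's MHC-B region).

Coding effect is computed for CDS SNPs only, by codon substitution under
the standard genetic code (stop gain/loss counts as non-synonymous);
Indels carry an insertion/deletion class instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .config import GeneModel, GenomicInterval, PipelineConfig
from .formats import VariantKey, ref_footprint, var_type

COMPONENT_PRECEDENCE = ("CDS", "utr5", "utr3", "intron", "promoter")


@dataclass(frozen=True)
class AnnotationRecord:
    key: VariantKey
    hits: tuple[tuple[str, str], ...]  # (gene_id, component), all overlapping genes
    effect: str  # synonymous | non-synonymous | non-coding
    indel_class: str  # insertion | deletion | not-applicable
    in_mrna: bool  # overlaps any exon
    in_gene: bool  # overlaps any gene body


def promoter_interval(
    gene: GeneModel, promoter_length: int, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Proximal promoter: ``promoter_length`` bp immediately upstream of the
    TSS, strand-aware, TSS excluded, clipped at chromosome bounds.

    Returns None when the gene starts at the chromosome edge and no
    upstream sequence exists.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = max(1, tss - promoter_length), tss - 1
    else:
        start, end = tss + 1, tss + promoter_length
        if chrom_length is not None:
            end = min(end, chrom_length)
    if start > end:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


class GeneIndex:
    """Interval index over gene bodies and promoters for fast lookup."""

    def __init__(
        self,
        models: list[GeneModel],
        promoter_length: int,
        chrom_lengths: dict[str, int] | None = None,
    ):
        self.models = {m.gene_id: m for m in models}
        self.promoter_length = promoter_length
        self._trees: dict[str, IntervalTree] = {}
        self._promoters: dict[str, GenomicInterval] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            span = m.span
            tree.addi(span.start, span.end + 1, m.gene_id)  # half-open tree coords
            clen = chrom_lengths.get(m.chrom) if chrom_lengths else None
            prom = promoter_interval(m, promoter_length, clen)
            if prom is not None:
                self._promoters[m.gene_id] = prom
                tree.addi(prom.start, prom.end + 1, m.gene_id)

    def genes_touching(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def promoter_of(self, gene_id: str) -> GenomicInterval | None:
        return self._promoters.get(gene_id)


def _component_for_gene(
    key: VariantKey, gene: GeneModel, promoter: GenomicInterval | None
) -> str | None:
    """Most specific component of ``gene`` overlapped by the variant
    footprint, or None when the variant misses both body and promoter."""
    fp = ref_footprint(key)
    s, e = fp.start, fp.end

    def any_overlap(segs) -> bool:
        return any(seg.overlaps(s, e) for seg in segs)

    if any_overlap(gene.cds_segments):
        return "CDS"
    if any_overlap(gene.utr5):
        return "utr5"
    if any_overlap(gene.utr3):
        return "utr3"
    if any_overlap(gene.introns()):
        return "intron"
    span = gene.span
    if span.overlaps(s, e):
        # exonic but neither CDS nor annotated UTR (non-coding exon sequence)
        return "utr5" if not gene.cds_segments else "intron"
    if promoter is not None and promoter.overlaps(s, e):
        return "promoter"
    return None


def locate(key: VariantKey, index: GeneIndex) -> tuple[tuple[str, str], ...]:
    """Per-gene component hits for a variant; empty tuple means intergenic."""
    fp = ref_footprint(key)
    hits = []
    for gene_id in index.genes_touching(fp.chrom, fp.start, fp.end):
        comp = _component_for_gene(key, index.models[gene_id], index.promoter_of(gene_id))
        if comp is not None:
            hits.append((gene_id, comp))
    return tuple(hits)


def cds_effect(key: VariantKey, gene: GeneModel, genome: dict[str, str]) -> str:
    """synonymous / non-synonymous call for a CDS SNP.

    The codon is located by the SNP's cumulative CDS offset in transcription
    order; on '-' strand genes both codon and alt base are
    reverse-complemented before translation (standard nuclear code).
    """
    if var_type(key) != "SNP":
        raise ValueError(f"{key}: cds_effect is defined for SNPs only")
    total = gene.cds_length()
    if total % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length {total} not divisible by 3")
    chrom_seq = genome[gene.chrom]

    # cumulative CDS offset of the SNP, in transcription order
    offset = None
    consumed = 0
    for seg in gene.cds_segments:
        if seg.contains(key.pos):
            within = (key.pos - seg.start) if gene.strand == "+" else (seg.end - key.pos)
            offset = consumed + within
            break
        consumed += seg.length
    if offset is None:
        raise ValueError(f"{key}: SNP not inside any CDS segment of {gene.gene_id}")

    # coding sequence in transcription order
    parts = []
    for seg in gene.cds_segments:
        s = chrom_seq[seg.start - 1 : seg.end]
        parts.append(s if gene.strand == "+" else str(Seq(s).reverse_complement()))
    cds = "".join(parts)
    if cds[offset] != (key.ref if gene.strand == "+" else str(Seq(key.ref).reverse_complement())):
        raise ValueError(
            f"{key}: reference allele disagrees with genome at CDS offset {offset}"
        )
    alt = key.alt if gene.strand == "+" else str(Seq(key.alt).reverse_complement())

    codon_start = (offset // 3) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = list(ref_codon)
    alt_codon[offset % 3] = alt
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


def indel_class(key: VariantKey) -> str:
    vt = var_type(key)  # raises on equal-length alleles
    if vt == "INS":
        return "insertion"
    if vt == "DEL":
        return "deletion"
    raise ValueError(f"{key}: indel_class is defined for INS/DEL only")


def annotate_key(
    key: VariantKey, index: GeneIndex, genome: dict[str, str]
) -> AnnotationRecord:
    hits = locate(key, index)
    vt = var_type(key)
    fp = ref_footprint(key)

    in_gene = any(
        index.models[g].span.overlaps(fp.start, fp.end) for g, _ in hits
    )
    in_mrna = any(
        any(e.overlaps(fp.start, fp.end) for e in index.models[g].exons)
        for g, _ in hits
    )

    if vt == "SNP":
        icls = "not-applicable"
        cds_genes = sorted(g for g, comp in hits if comp == "CDS")
        if cds_genes:
            effects = {cds_effect(key, index.models[g], genome) for g in cds_genes}
            effect = "non-synonymous" if "non-synonymous" in effects else "synonymous"
        else:
            effect = "non-coding"
    else:
        icls = indel_class(key)
        effect = "non-coding"

    return AnnotationRecord(
        key=key, hits=hits, effect=effect, indel_class=icls,
        in_mrna=in_mrna, in_gene=in_gene,
    )


def annotate_calls(
    keys: list[VariantKey],
    models: list[GeneModel],
    genome: dict[str, str],
    config: PipelineConfig,
) -> dict[VariantKey, AnnotationRecord]:
    """Annotate a set of unique variant keys against all gene models."""
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    index = GeneIndex(models, config.promoter_length, chrom_lengths)
    return {k: annotate_key(k, index, genome) for k in keys}
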