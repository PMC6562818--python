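"""Readers/writers for the standard formats the pipeline touches.

FASTA via Bio.SeqIO, GFF3 via gffutils; the samtools-style 6-column text
pileup parser and a minimal single-sample VCFv4.2 subset are implemented
here (the pileup grammar is this pipeline's input contract, and the VCF
subset stores exact p-values that a float32 INFO field would destroy).

Variant keys are canonical (chrom, pos, ref, alt) tuples, VCF-anchored for
indels (deletion: anchor+deleted vs anchor; insertion: anchor vs
anchor+inserted) and left-aligned against the reference.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, NamedTuple

import gffutils
from Bio import SeqIO

from .config import GeneModel, GenomicInterval, sort_intervals_tx_order


class FormatError(ValueError):
    """Malformed input in one of the supported file formats."""


# ---------------------------------------------------------------------------
# Variant keys


class VariantKey(NamedTuple):
    chrom: str
    pos: int  # 1-based anchor position
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def var_type(key: VariantKey) -> str:
    """Classify a key as SNP / INS / DEL from allele lengths."""
    if len(key.ref) == len(key.alt) == 1:
        return "SNP"
    if len(key.alt) > len(key.ref):
        return "INS"
    if len(key.ref) > len(key.alt):
        return "DEL"
    raise ValueError(f"unclassifiable key {key} (equal-length alleles)")


def ref_footprint(key: VariantKey) -> GenomicInterval:
    """Genomic interval covered by the key's reference allele."""
    return GenomicInterval(key.chrom, key.pos, key.pos + len(key.ref) - 1)


def left_align_key(key: VariantKey, chrom_seq: str) -> VariantKey:
    """Normalize an indel key: trim shared bases, then shift left while the
    flanking reference base equals the trailing indel base.

    SNP keys are returned unchanged.  ``chrom_seq`` is the full sequence of
    ``key.chrom`` (1-based positions index ``chrom_seq[pos - 1]``).
    """
    chrom, pos, ref, alt = key
    if len(ref) == 1 and len(alt) == 1:
        return key
    # trim identical trailing bases, extending left when an allele empties
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError(f"cannot left-extend {key} past chromosome start")
                pos -= 1
                b = chrom_seq[pos - 1].upper()
                ref, alt = b + ref, b + alt
        else:
            break
    # trim identical leading bases down to the single anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {chrom: uppercase sequence}.

    Headers are truncated at the first whitespace.  Duplicate ids and empty
    records are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(f"FASTA record {rec.id!r} has non-ACGTN bases {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _derive_utrs(
    strand: str,
    exons_tx: tuple[GenomicInterval, ...],
    cds_tx: tuple[GenomicInterval, ...],
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    """Project CDS onto exons: exonic sequence 5' of the CDS is 5'UTR,
    3' of it is 3'UTR (transcription order)."""
    if not cds_tx:
        return (), ()
    chrom = exons_tx[0].chrom
    if strand == "+":
        cds_lo = min(c.start for c in cds_tx)
        cds_hi = max(c.end for c in cds_tx)
    else:
        cds_lo = min(c.start for c in cds_tx)
        cds_hi = max(c.end for c in cds_tx)
    utr_left: list[GenomicInterval] = []  # genomic-left of CDS
    utr_right: list[GenomicInterval] = []
    for e in exons_tx:
        if e.end < cds_lo:
            utr_left.append(e)
        elif e.start < cds_lo <= e.end:
            utr_left.append(GenomicInterval(chrom, e.start, cds_lo - 1, strand))
        if e.start > cds_hi:
            utr_right.append(e)
        elif e.start <= cds_hi < e.end:
            utr_right.append(GenomicInterval(chrom, cds_hi + 1, e.end, strand))
    left = sort_intervals_tx_order(utr_left, strand)
    right = sort_intervals_tx_order(utr_right, strand)
    if strand == "+":
        return left, right
    return right, left


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3: one GeneModel per mRNA.

    Exon/CDS/UTR features are linked to their mRNA by Parent.  When the file
    carries no explicit UTR features they are derived by projecting the CDS
    onto the exons.  Orphan Parent references and CDS segments outside exons
    are errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in known_ids:
                raise FormatError(
                    f"feature {feat.id or feat.featuretype} references missing Parent {parent!r}"
                )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        strand = mrna.strand
        if strand not in {"+", "-"}:
            raise FormatError(f"mRNA {mrna.id}: strand must be + or -")
        chrom = mrna.seqid

        def _collect(ftype: str) -> list[GenomicInterval]:
            return [
                GenomicInterval(chrom, f.start, f.end, strand)
                for f in db.children(mrna, featuretype=ftype, order_by="start")
            ]

        exons = sort_intervals_tx_order(_collect("exon"), strand)
        if not exons:
            raise FormatError(f"mRNA {mrna.id} has no exons")
        cds = sort_intervals_tx_order(_collect("CDS"), strand)
        for seg in cds:
            if not any(e.start <= seg.start and seg.end <= e.end for e in exons):
                raise FormatError(
                    f"mRNA {mrna.id}: CDS {seg.start}-{seg.end} outside all exons"
                )
        utr5 = sort_intervals_tx_order(_collect("five_prime_UTR"), strand)
        utr3 = sort_intervals_tx_order(_collect("three_prime_UTR"), strand)
        if not utr5 and not utr3:
            utr5, utr3 = _derive_utrs(strand, exons, cds)
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_segments=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""

    def line(chrom, src, ftype, start, end, strand, attrs):
        return f"{chrom}\t{src}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            gid, tid = m.gene_id, f"{m.gene_id}.t1"
            fh.write(line(m.chrom, "poolvar", "gene", span.start, span.end, m.strand, f"ID={gid}"))
            fh.write(
                line(m.chrom, "poolvar", "mRNA", span.start, span.end, m.strand, f"ID={tid};Parent={gid}")
            )
            for ftype, segs in (
                ("exon", m.exons),
                ("CDS", m.cds_segments),
                ("five_prime_UTR", m.utr5),
                ("three_prime_UTR", m.utr3),
            ):
                for i, seg in enumerate(sorted(segs, key=lambda s: s.start), 1):
                    fh.write(
                        line(
                            m.chrom, "poolvar", ftype, seg.start, seg.end, m.strand,
                            f"ID={tid}.{ftype}.{i};Parent={tid}",
                        )
                    )


# ---------------------------------------------------------------------------
# samtools text pileup


class PileupSite(NamedTuple):
    """Per-site, per-pool allele counts parsed from a text pileup line.

    ``base_counts`` maps substitution alleles (A/C/G/T, reference matches
    counted under the reference base) and indel alleles (``+SEQ`` insertions,
    ``-SEQ`` deletions) to read counts.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int
    base_counts: dict[str, int]
    pool_id: str


class PileupParseError(FormatError):
    pass


def parse_pileup_line(line: str, pool_id: str) -> PileupSite:
    """Parse one 6-column samtools text pileup line.

    Read-bases grammar: ``.``/``,`` reference match; ``ACGTacgt`` mismatch;
    ``+n<seq>``/``-n<seq>`` indel following the anchor base; ``^X`` read
    start (the mapping-quality character X is skipped); ``$`` read end;
    ``*`` deletion placeholder (not counted as an observation).  Case is
    folded: the caller is strand-agnostic.
    """
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 6:
        cols = line.split()
    if len(cols) < 6:
        raise PileupParseError(f"expected 6 pileup columns, got {len(cols)}: {line!r}")
    chrom, pos_s, ref, depth_s, bases = cols[0], cols[1], cols[2], cols[3], cols[4]
    try:
        pos, depth = int(pos_s), int(depth_s)
    except ValueError as exc:
        raise PileupParseError(f"bad pos/depth in {line!r}") from exc
    ref = ref.upper()
    counts: dict[str, int] = {}
    observed = 0
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            counts[ref] = counts.get(ref, 0) + 1
            observed += 1
            i += 1
        elif c in "ACGTacgt":
            b = c.upper()
            counts[b] = counts.get(b, 0) + 1
            observed += 1
            i += 1
        elif c in "Nn":
            observed += 1
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"column {i}: '{c}' not followed by a length")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) < length:
                raise PileupParseError(
                    f"column {i}: truncated indel spec ({length} bases expected)"
                )
            allele = c + seq.upper()
            counts[allele] = counts.get(allele, 0) + 1
            i = j + length
        elif c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"column {i}: '^' at end of string")
            i += 2  # skip mapping-quality char
        elif c == "$":
            i += 1
        elif c == "*":
            observed += 1
            i += 1
        else:
            raise PileupParseError(f"column {i}: unexpected pileup symbol {c!r}")
    if observed != depth:
        warnings.warn(
            f"{chrom}:{pos}: pileup depth {depth} != {observed} parsed observations",
            stacklevel=2,
        )
    return PileupSite(chrom, pos, ref, depth, counts, pool_id)


def read_pileup(path: str | Path, pool_id: str) -> list[PileupSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sites.append(parse_pileup_line(line, pool_id))
    return sites


def iter_pileup(path: str | Path, pool_id: str):
    """Stream PileupSites from a file without holding them all in memory."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield parse_pileup_line(line, pool_id)


# ---------------------------------------------------------------------------
# VCF (minimal single-sample VCFv4.2 subset)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=poolvar
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pool read depth at site">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting read count">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alt read fraction (AC/DP)">
##INFO=<ID=PV,Number=1,Type=String,Description="Binomial upper-tail p-value vs base-error null (exact repr)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Pool-level genotype class: 1/1 fixed, 0/1 segregating">
"""


def write_vcf(calls, path: str | Path) -> None:
    """Write per-pool VariantCalls as a single-sample VCF.

    Calls must be sorted by (chrom, pos) and share one pool_id; only PASS
    records are emitted (the caller only produces PASS records).
    """
    calls = list(calls)
    pools = {c.pool_id for c in calls}
    if len(pools) > 1:
        raise FormatError(f"one VCF per pool: got pools {sorted(pools)}")
    pool = pools.pop() if pools else "POOL"
    keys = [(c.key.chrom, c.key.pos) for c in calls]
    if keys != sorted(keys):
        raise FormatError("calls must be sorted by (chrom, pos) before writing VCF")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{pool}\n")
        for c in calls:
            gt = "1/1" if c.zygosity_class == "pool-homozygous" else "0/1"
            info = f"DP={c.depth};AC={c.alt_count};AF={c.alt_fraction:.6g};PV={c.p_value!r}"
            fh.write(
                f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
            )


def read_vcf(path: str | Path):
    """Read a poolvar VCF back into VariantCalls (inverse of write_vcf)."""
    from .caller import VariantCall  # local import: avoid cycle

    calls = []
    pool = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) != 10:
                    raise FormatError(f"line {ln}: expected 10 header columns")
                pool = cols[9]
                continue
            cols = line.split("\t")
            if len(cols) != 10 or pool is None:
                raise FormatError(f"line {ln}: malformed VCF record")
            chrom, pos_s, _, ref, alt, _, filt, info_s, _, gt = cols
            try:
                pos = int(pos_s)
                info = dict(kv.split("=", 1) for kv in info_s.split(";"))
                depth = int(info["DP"])
                ac = int(info["AC"])
                pv = float(info["PV"])
            except (ValueError, KeyError) as exc:
                raise FormatError(f"line {ln}: malformed VCF record ({exc})") from exc
            if filt != "PASS":
                raise FormatError(f"line {ln}: only PASS records supported")
            key = VariantKey(chrom, pos, ref, alt)
            calls.append(
                VariantCall(
                    key=key,
                    var_type=var_type(key),
                    pool_id=pool,
                    depth=depth,
                    alt_count=ac,
                    zygosity_class=(
                        "pool-homozygous" if gt == "1/1" else "pool-heterozygous"
                    ),
                    p_value=pv,
                    passed_fdr=True,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based closed in memory)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {ln}: BED needs >=3 columns")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"line {ln}: bad BED coordinates") from exc
            regions.append(GenomicInterval(cols[0], start0 + 1, end0))
    return regions


def write_bed(regions: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
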