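"""Independent brute-force oracles and random-instance generators shared by
the unit and acceptance tests.  Everything here is deliberately naive and
separate from the package's implementation paths."""

from __future__ import annotations

import math
import random

from poolvar.config import GenomicInterval, GeneModel, sort_intervals_tx_order
from poolvar.formats import PileupSite, VariantKey

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Benjamini-Hochberg, literal O(m^2) step-up


def bh_bruteforce(pvals: list[float], q: float) -> list[bool]:
    m = len(pvals)
    if m == 0:
        return []
    best_r = 0
    for r in range(m, 0, -1):
        thresh = r * q / m
        if sum(1 for p in pvals if p <= thresh) >= r:
            best_r = r
            break
    cut = best_r * q / m if best_r else -1.0
    return [p <= cut for p in pvals]


# ---------------------------------------------------------------------------
# binomial upper tail by direct summation


def binom_tail(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


# ---------------------------------------------------------------------------
# caller: literal three-gate enumeration


def caller_bruteforce(sites: list[PileupSite], config) -> list[tuple[VariantKey, str]]:
    """Enumerate every site, apply depth gate, fraction gate and BH literally.
    Returns sorted (key, zygosity) pairs; no left-alignment (genome-free)."""
    cands = []
    for s in sites:
        if s.depth <= config.min_depth_exclusive:
            continue
        nonref = {a: c for a, c in s.base_counts.items() if a != s.ref_base and c > 0}
        if not nonref:
            continue
        allele, count = sorted(nonref.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if count / s.depth < config.het_fraction_min:
            continue
        cands.append((s, allele, count))
    pvals = [binom_tail(c, s.depth, config.base_error_rate) for s, _, c in cands]
    flags = bh_bruteforce(pvals, config.fdr_q)
    out = []
    for (s, allele, count), keep in zip(cands, flags):
        if not keep:
            continue
        if allele.startswith("+"):
            key = VariantKey(s.chrom, s.pos, s.ref_base, s.ref_base + allele[1:])
        elif allele.startswith("-"):
            key = VariantKey(s.chrom, s.pos, s.ref_base + allele[1:], s.ref_base)
        else:
            key = VariantKey(s.chrom, s.pos, s.ref_base, allele)
        zyg = (
            "pool-homozygous"
            if count / s.depth >= config.hom_fraction_min
            else "pool-heterozygous"
        )
        out.append((key, zyg))
    return sorted(out)


def random_sites(rng: random.Random, n_sites: int, pool: str = "P") -> list[PileupSite]:
    """Random per-site allele counts straddling every caller gate."""
    sites = []
    pos = 0
    for _ in range(n_sites):
        pos += rng.randint(1, 50)
        ref = rng.choice(BASES)
        depth = rng.randint(0, 40)
        counts: dict[str, int] = {}
        remaining = depth
        # up to two alternate alleles (substitution or indel), then ref fill
        for _ in range(rng.randint(0, 2)):
            if remaining == 0:
                break
            kind = rng.random()
            if kind < 0.6:
                allele = rng.choice([b for b in BASES if b != ref])
            elif kind < 0.8:
                allele = "+" + "".join(rng.choice(BASES) for _ in range(rng.randint(1, 4)))
            else:
                allele = "-" + "".join(rng.choice(BASES) for _ in range(rng.randint(1, 4)))
            c = rng.randint(1, remaining)
            counts[allele] = counts.get(allele, 0) + c
            remaining -= c
        if remaining:
            counts[ref] = remaining
        sites.append(PileupSite("chrR", pos, ref, depth, counts, pool))
    return sites


# ---------------------------------------------------------------------------
# pileup read-bases generator with its own tally


def random_pileup_line(rng: random.Random) -> tuple[str, dict[str, int], int]:
    """Assemble a random read-bases string from the grammar; return the
    line, the expected allele tally, and the expected observation count."""
    ref = rng.choice(BASES)
    tally: dict[str, int] = {}
    observed = 0
    parts = []
    for _ in range(rng.randint(0, 30)):
        r = rng.random()
        if r < 0.10:  # read start marker + mapping quality char
            parts.append("^" + chr(rng.randint(33, 126)))
            continue
        if r < 0.18:
            parts.append("$")
            continue
        if r < 0.26:
            parts.append("*")
            observed += 1
            continue
        if r < 0.40:
            length = rng.randint(1, 12)
            seq = "".join(rng.choice(BASES) for _ in range(length))
            sign = rng.choice("+-")
            shown = seq.lower() if rng.random() < 0.5 else seq
            parts.append(f".{sign}{length}{shown}")
            tally[ref] = tally.get(ref, 0) + 1
            allele = sign + seq
            tally[allele] = tally.get(allele, 0) + 1
            observed += 1
            continue
        if r < 0.75:
            parts.append(rng.choice(".,"))
            tally[ref] = tally.get(ref, 0) + 1
            observed += 1
            continue
        b = rng.choice(BASES)
        parts.append(b.lower() if rng.random() < 0.5 else b)
        tally[b] = tally.get(b, 0) + 1
        observed += 1
    bases = "".join(parts) or "."
    if bases == ".":
        tally[ref] = 1
        observed = 1
    line = f"chrZ\t100\t{ref}\t{observed}\t{bases}\t{'I' * max(observed, 1)}"
    return line, tally, observed


# ---------------------------------------------------------------------------
# random gene models and their strand mirror


def random_plus_gene(rng: random.Random, genome_len: int, gene_id: str = "gZ") -> GeneModel:
    """Random multi-exon '+' strand gene with a frame-complete CDS."""
    n_exons = rng.randint(2, 4)
    start = rng.randint(50, genome_len // 3)
    exons = []
    cur = start
    for _ in range(n_exons):
        ln = rng.randint(60, 200)
        exons.append(GenomicInterval("chrM", cur, cur + ln - 1, "+"))
        cur += ln + rng.randint(40, 150)
    u5 = rng.randint(5, 40)
    u3 = rng.randint(5, 40)
    total = sum(e.length for e in exons)
    cds_len = total - u5 - u3
    u3 += cds_len % 3
    cds_len -= cds_len % 3
    assert cds_len >= 3
    # walk exons assigning utr5 | cds | utr3 by cumulative position
    cds, utr5, utr3 = [], [], []
    consumed = 0
    for e in exons:
        for lo, hi, bucket in _split_exon(consumed, e, u5, u5 + cds_len):
            bucket_list = {0: utr5, 1: cds, 2: utr3}[bucket]
            bucket_list.append(GenomicInterval("chrM", lo, hi, "+"))
        consumed += e.length
    return GeneModel(
        gene_id=gene_id, chrom="chrM", strand="+",
        exons=tuple(exons), cds_segments=tuple(cds),
        utr5=tuple(utr5), utr3=tuple(utr3),
    )


def _split_exon(consumed: int, e: GenomicInterval, cds_from: int, cds_to: int):
    """Split one exon into (start, end, bucket) runs by cumulative offset:
    bucket 0 before cds_from, 1 in [cds_from, cds_to), 2 after."""
    out = []
    for off in range(e.length):
        cum = consumed + off
        bucket = 0 if cum < cds_from else (1 if cum < cds_to else 2)
        pos = e.start + off
        if out and out[-1][2] == bucket:
            out[-1] = (out[-1][0], pos, bucket)
        else:
            out.append((pos, pos, bucket))
    return out


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mirror_gene(gene: GeneModel, genome_len: int) -> GeneModel:
    """The same gene expressed on the reverse-complemented genome: '-' strand,
    coordinates flipped around the sequence midpoint."""

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.chrom, genome_len - iv.end + 1, genome_len - iv.start + 1, "-")

    return GeneModel(
        gene_id=gene.gene_id, chrom=gene.chrom, strand="-",
        exons=sort_intervals_tx_order([flip(e) for e in gene.exons], "-"),
        cds_segments=sort_intervals_tx_order([flip(c) for c in gene.cds_segments], "-"),
        utr5=sort_intervals_tx_order([flip(u) for u in gene.utr5], "-"),
        utr3=sort_intervals_tx_order([flip(u) for u in gene.utr3], "-"),
    )
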