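"""Synthetic data: genomes, gene models, planted variant truth sets and
noisy pool pileups.

The generator emulates the study design the pipeline targets: four pools
(two breeds x high/low IgY, 10 diploid birds per pool, so pool allele
fractions are multiples of 1/20), capture-style contiguous regions, a
planted variant structure spanning every breed-/group-specific category
including same-position-different-allele pairs, and at least one
overlapping gene pair where one gene's 3'UTR sits inside another gene's
intron (the TAP1/BF1 configuration).

Noise model: per-site depth ~ Poisson(depth_mean); at a truth site carried
by the pool, alt reads ~ Binomial(depth, f*(1-eps)); elsewhere errors ~
Binomial(depth, eps) spread uniformly over the three non-reference bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .caller import VariantCall
from .compare import POOLS, ComparisonResult, PresenceMatrix
from .config import GeneModel, GenomicInterval, parse_flat_keyvalue, sort_intervals_tx_order
from .formats import VariantKey, left_align_key, var_type

TRUTH_CATEGORIES = (
    "BY-shared",
    "BY-high-specific",
    "BY-low-specific",
    "WL-shared",
    "WL-high-specific",
    "WL-low-specific",
    "common-high",
    "common-low",
    "same-pos-diff-high",
    "same-pos-diff-low",
)

_CATEGORY_POOLS: dict[str, frozenset[str]] = {
    "BY-shared": frozenset({"BY-H", "BY-L"}),
    "BY-high-specific": frozenset({"BY-H"}),
    "BY-low-specific": frozenset({"BY-L"}),
    "WL-shared": frozenset({"WL-H", "WL-L"}),
    "WL-high-specific": frozenset({"WL-H"}),
    "WL-low-specific": frozenset({"WL-L"}),
    "common-high": frozenset({"BY-H", "WL-H"}),
    "common-low": frozenset({"BY-L", "WL-L"}),
}

# mapping to the comparator's seven-way partition
EXPECTED_PARTITION = {
    "BY-shared": "BY-only-shared",
    "BY-high-specific": "BY-only-high-specific",
    "BY-low-specific": "BY-only-low-specific",
    "WL-shared": "WL-only-shared",
    "WL-high-specific": "WL-only-high-specific",
    "WL-low-specific": "WL-only-low-specific",
    "common-high": "both-breeds",
    "common-low": "both-breeds",
}


@dataclass(frozen=True)
class TruthDesign:
    """Planted-variant design for one simulated experiment.

    Per-category counts are per breed where the category is breed-local.
    ``same_pos_diff_*_pairs`` plant two records with distinct alternate
    alleles at one position, one per breed's high (or low) pool.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr16sim", 35000), ("chr11sim", 35000))
    n_genes: int = 10
    overlapping_gene_pairs: int = 1
    breed_shared: int = 30
    breed_high_only: int = 20
    breed_low_only: int = 20
    cross_common_high: int = 25
    cross_common_low: int = 25
    same_pos_diff_high_pairs: int = 5
    same_pos_diff_low_pairs: int = 5
    snp_fraction: float = 0.7
    depth_mean: float = 30.0
    seq_error_rate: float = 0.0
    n_individuals_per_pool: int = 10

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name in {"snp_fraction", "seq_error_rate", "chrom_lengths"}:
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if not (0 <= self.snp_fraction <= 1):
            raise ValueError("snp_fraction must be in [0,1]")
        if not (0 <= self.seq_error_rate < 0.5):
            raise ValueError("seq_error_rate must be in [0,0.5)")

    @property
    def n_truth_records(self) -> int:
        return (
            2 * (self.breed_shared + self.breed_high_only + self.breed_low_only)
            + self.cross_common_high
            + self.cross_common_low
            + 2 * (self.same_pos_diff_high_pairs + self.same_pos_diff_low_pairs)
        )

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name == "chrom_lengths":
                v = ",".join(f"{c}={L}" for c, L in v)
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "TruthDesign":
        mapping = parse_flat_keyvalue(Path(path).read_text())
        kwargs: dict = {}
        for key, val in mapping.items():
            if key == "chrom_lengths":
                kwargs[key] = tuple(
                    (c, int(L)) for c, L in (item.split("=") for item in val.split(","))
                )
            elif key in {"snp_fraction", "depth_mean", "seq_error_rate"}:
                kwargs[key] = float(val)
            else:
                kwargs[key] = int(val)
        return cls(**kwargs)


@dataclass(frozen=True)
class TruthRecord:
    key: VariantKey
    category: str
    pools: frozenset[str]
    fraction: float  # intended pool alt-allele fraction

    def __post_init__(self) -> None:
        if self.category not in TRUTH_CATEGORIES:
            raise ValueError(f"unknown truth category {self.category}")
        expected = _CATEGORY_POOLS.get(self.category)
        if expected is not None and self.pools != expected:
            raise ValueError(
                f"{self.category}: pools {sorted(self.pools)} != {sorted(expected)}"
            )
        if self.category.startswith("same-pos-diff") and len(self.pools) != 1:
            raise ValueError(f"{self.category}: expected a single pool")
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction {self.fraction} outside (0,1]")


# ---------------------------------------------------------------------------
# genome


def make_genome(design: TruthDesign, seed: int) -> dict[str, str]:
    """I.i.d. uniform ACGT sequences, one per design chromosome."""
    for chrom, length in design.chrom_lengths:
        if length < 10_000:
            raise ValueError(f"{chrom}: length {length} < 10 kb minimum")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        chrom: rng.choice(bases, size=length).tobytes().decode()
        for chrom, length in design.chrom_lengths
    }


# ---------------------------------------------------------------------------
# gene models


def _single_gene(chrom: str, start: int, strand: str, gene_id: str, rng) -> GeneModel:
    """Three-exon gene with 5'/3' UTRs and a frame-complete CDS."""
    e1 = int(rng.integers(250, 351))
    i1 = int(rng.integers(300, 501))
    e2 = int(rng.integers(300, 451))
    i2 = int(rng.integers(300, 501))
    e3 = int(rng.integers(250, 351))
    s1, e1_end = start, start + e1 - 1
    s2, e2_end = e1_end + i1 + 1, e1_end + i1 + e2
    s3, e3_end = e2_end + i2 + 1, e2_end + i2 + e3
    exons_g = [
        GenomicInterval(chrom, s1, e1_end, strand),
        GenomicInterval(chrom, s2, e2_end, strand),
        GenomicInterval(chrom, s3, e3_end, strand),
    ]
    u5, u3 = 100, 100
    cds_len = (e1 - u5) + e2 + (e3 - u3)
    u3 += cds_len % 3  # keep CDS length divisible by 3
    if strand == "+":
        cds = (
            GenomicInterval(chrom, s1 + u5, e1_end, strand),
            exons_g[1],
            GenomicInterval(chrom, s3, e3_end - u3, strand),
        )
        utr5 = (GenomicInterval(chrom, s1, s1 + u5 - 1, strand),)
        utr3 = (GenomicInterval(chrom, e3_end - u3 + 1, e3_end, strand),)
    else:
        cds = (
            GenomicInterval(chrom, s3, e3_end - u5, strand),
            exons_g[1],
            GenomicInterval(chrom, s1 + u3, e1_end, strand),
        )
        utr5 = (GenomicInterval(chrom, e3_end - u5 + 1, e3_end, strand),)
        utr3 = (GenomicInterval(chrom, s1, s1 + u3 - 1, strand),)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=sort_intervals_tx_order(exons_g, strand),
        cds_segments=sort_intervals_tx_order(cds, strand),
        utr5=utr5,
        utr3=utr3,
    )


def _overlap_pair(chrom: str, start: int, ids: tuple[str, str]) -> tuple[GeneModel, GeneModel]:
    """Two genes where gene A's 3'UTR lies inside gene B's intron.

    Fixed-layout construction (relative to ``start``): A spans [0, 4000]
    with its second exon [3600, 4000] entirely inside B's intron
    [3101, 6199]; A's 3'UTR occupies the tail of that exon.
    """
    s = start
    a_id, b_id = ids

    # gene A: '+', exons [s, s+500] and [s+3600, s+4000]
    a_exons = (
        GenomicInterval(chrom, s, s + 500, "+"),
        GenomicInterval(chrom, s + 3600, s + 4000, "+"),
    )
    a_cds_len = 401 + 201
    trim = a_cds_len % 3
    a_cds = (
        GenomicInterval(chrom, s + 100, s + 500, "+"),
        GenomicInterval(chrom, s + 3600, s + 3800 - trim, "+"),
    )
    gene_a = GeneModel(
        gene_id=a_id, chrom=chrom, strand="+",
        exons=a_exons, cds_segments=a_cds,
        utr5=(GenomicInterval(chrom, s, s + 99, "+"),),
        utr3=(GenomicInterval(chrom, s + 3801 - trim, s + 4000, "+"),),
    )

    # gene B: '+', exons [s+2600, s+3100] and [s+6200, s+6800]
    b_exons = (
        GenomicInterval(chrom, s + 2600, s + 3100, "+"),
        GenomicInterval(chrom, s + 6200, s + 6800, "+"),
    )
    b_cds_len = 401 + 501
    trim_b = b_cds_len % 3
    b_cds = (
        GenomicInterval(chrom, s + 2700, s + 3100, "+"),
        GenomicInterval(chrom, s + 6200, s + 6700 - trim_b, "+"),
    )
    gene_b = GeneModel(
        gene_id=b_id, chrom=chrom, strand="+",
        exons=b_exons, cds_segments=b_cds,
        utr5=(GenomicInterval(chrom, s + 2600, s + 2699, "+"),),
        utr3=(GenomicInterval(chrom, s + 6701 - trim_b, s + 6800, "+"),),
    )
    return gene_a, gene_b


_PROMOTER_LEADIN = 2100  # room for a 2 kb promoter before each gene
_GENE_GAP = 400


def make_gene_models(genome: Mapping[str, str], design: TruthDesign, seed: int) -> list[GeneModel]:
    """Pack multi-exon genes onto the genome, alternating strands, with the
    requested number of 3'UTR-in-intron overlapping pairs."""
    if design.n_genes == 0:
        return []
    if design.n_genes < 2 * design.overlapping_gene_pairs:
        raise ValueError("n_genes too small for requested overlapping pairs")
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    models: list[GeneModel] = []
    cursors = {c: _PROMOTER_LEADIN for c in chroms}
    chrom_i = 0
    pairs_left = design.overlapping_gene_pairs
    singles_left = design.n_genes - 2 * design.overlapping_gene_pairs
    gid = 0
    while pairs_left or singles_left:
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[chrom_i % len(chroms)]
            chrom_i += 1
            cur = cursors[chrom]
            if pairs_left:
                need = 6800 + _GENE_GAP
                if cur + need <= len(genome[chrom]):
                    a, b = _overlap_pair(chrom, cur, (f"gene{gid:02d}", f"gene{gid + 1:02d}"))
                    models.extend([a, b])
                    gid += 2
                    cursors[chrom] = cur + need + _PROMOTER_LEADIN
                    pairs_left -= 1
                    placed = True
                    break
            else:
                strand = "+" if rng.integers(2) == 0 else "-"
                gene = _single_gene(chrom, cur, strand, f"gene{gid:02d}", rng)
                need = gene.span.length + _GENE_GAP
                if cur + need + _PROMOTER_LEADIN <= len(genome[chrom]):
                    models.append(gene)
                    gid += 1
                    cursors[chrom] = cur + need + _PROMOTER_LEADIN
                    singles_left -= 1
                    placed = True
                    break
        if not placed:
            raise ValueError(
                "cannot pack requested genes: enlarge the genome or reduce n_genes"
            )
    return models


# ---------------------------------------------------------------------------
# variant planting


def _component_spaces(genome, models, promoter_length=2000):
    """Candidate position lists per component class."""
    from .annotate import promoter_interval

    spaces: dict[str, list[tuple[str, int, int]]] = {
        "CDS": [], "promoter": [], "utr": [], "intron": [],
    }
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for m in models:
        for seg in m.cds_segments:
            spaces["CDS"].append((m.chrom, seg.start, seg.end))
        for seg in list(m.utr5) + list(m.utr3):
            spaces["utr"].append((m.chrom, seg.start, seg.end))
        for seg in m.introns():
            spaces["intron"].append((m.chrom, seg.start, seg.end))
        prom = promoter_interval(m, promoter_length, len(genome[m.chrom]))
        if prom is not None:
            spaces["promoter"].append((m.chrom, prom.start, prom.end))
        covered[m.chrom].append((m.span.start, m.span.end))
        if prom is not None:
            covered[m.chrom].append((prom.start, prom.end))
    intergenic = []
    for chrom, seq in genome.items():
        ivs = sorted(covered[chrom])
        cur = 30  # keep clear of the chromosome edge (left-alignment, footprints)
        for s, e in ivs:
            if s - 1 >= cur:
                intergenic.append((chrom, cur, s - 1))
            cur = max(cur, e + 1)
        if cur <= len(seq) - 30:
            intergenic.append((chrom, cur, len(seq) - 30))
    spaces["intergenic"] = intergenic
    return spaces


_COMPONENT_WEIGHTS = {"CDS": 0.25, "promoter": 0.20, "utr": 0.10, "intron": 0.15, "intergenic": 0.30}
_MIN_SPACING = 20  # bp between planted anchors: keeps indel footprints disjoint


class _PositionSampler:
    def __init__(self, genome, spaces, rng):
        self.genome = genome
        self.spaces = spaces
        self.rng = rng
        self.used: dict[str, set[int]] = {c: set() for c in genome}

    def _free(self, chrom: str, pos: int) -> bool:
        lo, hi = pos - _MIN_SPACING, pos + _MIN_SPACING
        return not any(p in self.used[chrom] for p in range(lo, hi + 1))

    def reserve(self, chrom: str, pos: int) -> None:
        self.used[chrom].add(pos)

    def sample(self, component: str) -> tuple[str, int]:
        ivs = self.spaces[component]
        if not ivs:
            raise ValueError(f"no genomic space available for component {component!r}")
        for _ in range(4000):
            chrom, s, e = ivs[int(self.rng.integers(len(ivs)))]
            # leave room for deletions/footprints at interval edges
            if e - s < 2:
                continue
            pos = int(self.rng.integers(s, e + 1))
            if pos < 15 or pos > len(self.genome[chrom]) - 15:
                continue
            if self._free(chrom, pos):
                self.reserve(chrom, pos)
                return chrom, pos
        raise ValueError(
            f"could not place variant in component {component!r}: space exhausted "
            "(design demands more variants than the component can hold)"
        )


_BASES = "ACGT"


def plant_variants(
    genome: Mapping[str, str], models: Sequence[GeneModel], design: TruthDesign, seed: int
) -> list[TruthRecord]:
    """Plant a truth set with exact per-category counts.

    Variants are spread over CDS/promoter/UTR/intron/intergenic space with
    fixed weights; intended pool allele fractions are multiples of
    1/(2 * n_individuals_per_pool) drawn from [0.5, 1].
    """
    rng = np.random.default_rng(seed)
    spaces = _component_spaces(genome, models)
    sampler = _PositionSampler(genome, spaces, rng)
    comp_names = list(_COMPONENT_WEIGHTS)
    comp_probs = np.array([_COMPONENT_WEIGHTS[c] for c in comp_names])
    comp_probs = comp_probs / comp_probs.sum()
    two_n = 2 * max(design.n_individuals_per_pool, 1)

    def rand_fraction() -> float:
        k = int(rng.integers(two_n // 2, two_n + 1))  # >= 0.5, multiple of 1/2N
        return k / two_n

    def pick_component(snp: bool) -> str:
        comp = str(rng.choice(comp_names, p=comp_probs))
        if not snp and comp == "CDS":
            comp = "intron"  # keep coding frames intact; indel effects are positional only
        return comp

    def make_snp_key(chrom: str, pos: int, n_alts: int = 1) -> list[VariantKey]:
        ref = genome[chrom][pos - 1]
        alts = rng.choice([b for b in _BASES if b != ref], size=n_alts, replace=False)
        return [VariantKey(chrom, pos, ref, str(a)) for a in alts]

    def make_indel_key(chrom: str, pos: int) -> VariantKey:
        seq = genome[chrom]
        length = int(rng.integers(1, 10))
        if rng.integers(2) == 0 and pos + length + 2 < len(seq):  # deletion
            ref = seq[pos - 1 : pos + length]
            key = VariantKey(chrom, pos, ref, ref[0])
        else:  # insertion
            ins = "".join(str(b) for b in rng.choice(list(_BASES), size=length))
            anchor = seq[pos - 1]
            key = VariantKey(chrom, pos, anchor, anchor + ins)
        return left_align_key(key, seq)

    records: list[TruthRecord] = []
    keys_seen: set[VariantKey] = set()

    def add(key: VariantKey, category: str, pools: frozenset[str], fraction: float) -> None:
        if key in keys_seen:
            raise ValueError(f"duplicate planted key {key}")
        keys_seen.add(key)
        records.append(TruthRecord(key, category, pools, fraction))

    def plant_category(count: int, category: str) -> None:
        pools = _CATEGORY_POOLS[category]
        for _ in range(count):
            snp = bool(rng.random() < design.snp_fraction)
            chrom, pos = sampler.sample(pick_component(snp))
            key = make_snp_key(chrom, pos)[0] if snp else make_indel_key(chrom, pos)
            add(key, category, pools, rand_fraction())

    for breed in ("BY", "WL"):
        plant_category(design.breed_shared, f"{breed}-shared")
        plant_category(design.breed_high_only, f"{breed}-high-specific")
        plant_category(design.breed_low_only, f"{breed}-low-specific")

    # one cross-breed common deletion is forced into the overlap region when
    # the design carries an overlapping gene pair (3'UTR-in-intron case)
    forced_common_high = 0
    if design.overlapping_gene_pairs and design.cross_common_high:
        overlap = _find_overlap_region(models)
        if overlap is not None:
            chrom, s, e = overlap
            pos = (s + e) // 2
            if sampler._free(chrom, pos):
                sampler.reserve(chrom, pos)
                ref = genome[chrom][pos - 1 : pos + 9]
                key = left_align_key(VariantKey(chrom, pos, ref, ref[0]), genome[chrom])
                if key not in keys_seen:
                    add(key, "common-high", _CATEGORY_POOLS["common-high"], rand_fraction())
                    forced_common_high = 1
    plant_category(design.cross_common_high - forced_common_high, "common-high")
    plant_category(design.cross_common_low, "common-low")

    for group, n_pairs in (
        ("high", design.same_pos_diff_high_pairs),
        ("low", design.same_pos_diff_low_pairs),
    ):
        for _ in range(n_pairs):
            chrom, pos = sampler.sample(pick_component(snp=True))
            k1, k2 = make_snp_key(chrom, pos, n_alts=2)
            cat = f"same-pos-diff-{group}"
            suffix = "H" if group == "high" else "L"
            add(k1, cat, frozenset({f"BY-{suffix}"}), rand_fraction())
            add(k2, cat, frozenset({f"WL-{suffix}"}), rand_fraction())

    records.sort(key=lambda r: r.key)
    return records


def _find_overlap_region(models: Sequence[GeneModel]) -> tuple[str, int, int] | None:
    """First region where one gene's 3'UTR intersects another's intron."""
    for a in models:
        for b in models:
            if a.gene_id == b.gene_id or a.chrom != b.chrom:
                continue
            for u in a.utr3:
                for i in b.introns():
                    lo, hi = max(u.start, i.start), min(u.end, i.end)
                    if lo + 12 <= hi:  # room for a 9 bp deletion footprint
                        return a.chrom, lo, hi - 12
    return None


# ---------------------------------------------------------------------------
# pileup simulation


def simulate_pool_pileup(
    genome: Mapping[str, str],
    truth: Sequence[TruthRecord],
    pool_id: str,
    design: TruthDesign,
    seed: int,
    out_path: str | Path,
) -> Path:
    """Write a 6-column text pileup for one pool.

    Truth sites carried by the pool emit alt reads at Binomial(depth,
    f*(1-eps)); every other site emits Binomial(depth, eps) error reads
    spread uniformly over the three non-reference bases.  Deleted bases
    downstream of a deletion anchor are rendered as '*' placeholders.
    Zero-depth sites are omitted (samtools convention).
    """
    if pool_id not in POOLS:
        raise ValueError(f"unknown pool {pool_id!r}")
    eps = design.seq_error_rate
    rng = np.random.default_rng([seed & 0x7FFFFFFF, POOLS.index(pool_id)])

    # per-chrom: anchor -> record; deletion shadows: pos -> fraction
    anchors: dict[str, dict[int, TruthRecord]] = {c: {} for c in genome}
    shadows: dict[str, dict[int, float]] = {c: {} for c in genome}
    for rec in truth:
        if pool_id not in rec.pools:
            continue
        if rec.key.pos in anchors[rec.key.chrom]:
            raise ValueError(f"two truth records for pool {pool_id} at {rec.key.chrom}:{rec.key.pos}")
        anchors[rec.key.chrom][rec.key.pos] = rec
        if var_type(rec.key) == "DEL":
            for p in range(rec.key.pos + 1, rec.key.pos + len(rec.key.ref)):
                shadows[rec.key.chrom][p] = rec.fraction

    out_path = Path(out_path)
    other = {b: [x for x in _BASES if x != b] for b in _BASES}
    with open(out_path, "w") as fh:
        for chrom, seq in genome.items():
            L = len(seq)
            depths = rng.poisson(design.depth_mean, L)
            err_counts = (
                rng.binomial(depths, eps) if eps > 0 else np.zeros(L, dtype=int)
            )
            ch_anchors = anchors[chrom]
            ch_shadows = shadows[chrom]
            lines = []
            for i in range(L):
                depth = int(depths[i])
                if depth == 0:
                    continue
                pos = i + 1
                ref = seq[i]
                rec = ch_anchors.get(pos)
                if rec is not None:
                    a = int(rng.binomial(depth, rec.fraction * (1.0 - eps)))
                    key = rec.key
                    vt = var_type(key)
                    if vt == "SNP":
                        # mixed case exercises the parser's strand folding
                        half = a // 2
                        tok = key.alt * half + key.alt.lower() * (a - half)
                    elif vt == "INS":
                        ins = key.alt[1:]
                        tok = f".+{len(ins)}{ins}" * a
                    else:  # DEL
                        dseq = key.ref[1:]
                        tok = f".-{len(dseq)}{dseq}" * a
                    bases = tok + "." * (depth - a)
                elif pos in ch_shadows:
                    a = int(rng.binomial(depth, ch_shadows[pos] * (1.0 - eps)))
                    bases = "*" * a + "." * (depth - a)
                else:
                    e = int(err_counts[i])
                    if e == 0:
                        bases = "." * depth
                    else:
                        e = min(e, depth)
                        errs = rng.choice(other[ref], size=e)
                        bases = "".join(errs) + "." * (depth - e)
                lines.append(f"{chrom}\t{pos}\t{ref}\t{depth}\t{bases}\t{'I' * min(depth, 40)}")
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    return out_path


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# poolvar truth set; seed={seed}\n")
        fh.write("chrom\tpos\tref\talt\tcategory\tpools\tfraction\n")
        for r in truth:
            fh.write(
                f"{r.key.chrom}\t{r.key.pos}\t{r.key.ref}\t{r.key.alt}\t"
                f"{r.category}\t{','.join(sorted(r.pools))}\t{r.fraction:g}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chrom\t") or not line.strip():
                continue
            chrom, pos, ref, alt, cat, pools, frac = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    VariantKey(chrom, int(pos), ref, alt),
                    cat,
                    frozenset(pools.split(",")),
                    float(frac),
                )
            )
    return records


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    truth: Sequence[TruthRecord],
    matrix: PresenceMatrix,
    result: ComparisonResult,
) -> tuple[float, float]:
    """(precision, recall) of planted-category recovery, both in [0, 1].

    A truth record is recovered when its key is present with exactly the
    intended pools, the comparator assigns the expected partition category,
    and (for cross-breed categories) it appears in the expected common set
    with the expected match type.  Precision asks the reverse: every
    presence-matrix row must trace back to a recovered truth record.
    """
    same_high = {p.key_by for p in result.common_high if p.match_type == "same-type"}
    same_low = {p.key_by for p in result.common_low if p.match_type == "same-type"}
    diff_high = {
        k for p in result.common_high if p.match_type == "different-type"
        for k in (p.key_by, p.key_wl)
    }
    diff_low = {
        k for p in result.common_low if p.match_type == "different-type"
        for k in (p.key_by, p.key_wl)
    }

    def recovered(rec: TruthRecord) -> bool:
        pools = matrix.rows.get(rec.key)
        if pools is None or pools != rec.pools:
            return False
        cat = rec.category
        if cat in EXPECTED_PARTITION:
            if result.categories[rec.key] != EXPECTED_PARTITION[cat]:
                return False
        if cat == "common-high" and rec.key not in same_high:
            return False
        if cat == "common-low" and rec.key not in same_low:
            return False
        if cat == "same-pos-diff-high":
            expect = "BY-only-high-specific" if "BY-H" in rec.pools else "WL-only-high-specific"
            if result.categories[rec.key] != expect or rec.key not in diff_high:
                return False
        if cat == "same-pos-diff-low":
            expect = "BY-only-low-specific" if "BY-L" in rec.pools else "WL-only-low-specific"
            if result.categories[rec.key] != expect or rec.key not in diff_low:
                return False
        return True

    n_recovered = sum(recovered(r) for r in truth)
    recall = n_recovered / len(truth) if truth else 1.0
    truth_recovered_keys = {r.key for r in truth if recovered(r)}
    n_rows = len(matrix.rows)
    precision = (
        sum(k in truth_recovered_keys for k in matrix.rows) / n_rows if n_rows else 1.0
    )
    return precision, recall


def false_discovery_proportion(
    calls_by_pool: Mapping[str, Sequence[VariantCall]],
    truth: Sequence[TruthRecord],
) -> float:
    """Fraction of called unique variant keys absent from the truth set."""
    called = {c.key for calls in calls_by_pool.values() for c in calls}
    if not called:
        return 0.0
    truth_keys = {r.key for r in truth}
    return sum(k not in truth_keys for k in called) / len(called)
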