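"""Per-pool SNP/Indel calling from pileup sites.

Calling gates, applied per pool:

1. depth strictly greater than ``min_depth_exclusive`` (coverage > 4);
2. modal non-reference allele fraction >= ``het_fraction_min``;
3. Benjamini-Hochberg FDR < ``fdr_q`` over binomial upper-tail p-values
   P[X >= alt_count | X ~ Bin(depth, base_error_rate)] computed jointly for
   every candidate site of the pool.

Pool-level zygosity is a fraction heuristic: alt fraction >=
``hom_fraction_min`` means the variant looks fixed in the pool
("pool-homozygous"); anything between the het and hom gates is segregating
("pool-heterozygous").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .formats import PileupSite, VariantKey, left_align_key, var_type


@dataclass(frozen=True)
class VariantCall:
    key: VariantKey
    var_type: str  # SNP | INS | DEL
    pool_id: str
    depth: int
    alt_count: int
    zygosity_class: str  # pool-homozygous | pool-heterozygous
    p_value: float
    passed_fdr: bool = True

    def __post_init__(self) -> None:
        if self.alt_count > self.depth:
            raise ValueError(f"{self.key}: alt_count {self.alt_count} > depth {self.depth}")
        if self.var_type not in {"SNP", "INS", "DEL"}:
            raise ValueError(f"bad var_type {self.var_type}")
        if self.zygosity_class not in {"pool-homozygous", "pool-heterozygous"}:
            raise ValueError(f"bad zygosity_class {self.zygosity_class}")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth


def site_pvalue(alt_count: int, depth: int, error_rate: float) -> float:
    """Upper-tail binomial p-value P[X >= alt_count], X ~ Bin(depth, error_rate).

    The null is that every alt read is a sequencing error.  Monotone
    non-increasing in alt_count at fixed depth; alt_count = 0 gives 1.0.
    """
    if not (0 <= alt_count <= depth):
        raise ValueError(f"alt_count {alt_count} outside [0, depth={depth}]")
    if not (0 < error_rate < 1):
        raise ValueError(f"error_rate {error_rate} outside (0,1)")
    if alt_count == 0:
        return 1.0
    return float(binom.sf(alt_count - 1, depth, error_rate))


def bh_fdr(p_values: Sequence[float], q: float) -> list[bool]:
    """Benjamini-Hochberg step-up: flags True for rejected (significant) tests.

    Original input order is preserved; ties share a fate.
    """
    if not (0 < q < 1):
        raise ValueError(f"q must be in (0,1), got {q}")
    p_values = list(p_values)
    if not p_values:
        return []
    for p in p_values:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0,1]")
    reject, _, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


def classify_zygosity(alt_fraction: float, config: PipelineConfig) -> str:
    if not (0 < alt_fraction <= 1):
        raise ValueError(f"alt_fraction {alt_fraction} outside (0,1]")
    if alt_fraction < config.het_fraction_min:
        raise ValueError(
            f"alt_fraction {alt_fraction} below het gate {config.het_fraction_min}: "
            "candidate should have been filtered upstream"
        )
    return "pool-homozygous" if alt_fraction >= config.hom_fraction_min else "pool-heterozygous"


def _modal_alt(site: PileupSite) -> tuple[str, int] | None:
    """Most frequent non-reference allele; ties broken lexicographically."""
    candidates = [
        (allele, n)
        for allele, n in site.base_counts.items()
        if allele != site.ref_base and n > 0
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda kv: (-kv[1], kv[0]))


def _allele_to_key(site: PileupSite, allele: str, genome: dict[str, str] | None) -> VariantKey:
    """Build a VCF-anchored variant key from a pileup allele string."""
    if allele.startswith("+"):  # insertion after the anchor base
        key = VariantKey(site.chrom, site.pos, site.ref_base, site.ref_base + allele[1:])
    elif allele.startswith("-"):  # deletion of the bases following the anchor
        key = VariantKey(site.chrom, site.pos, site.ref_base + allele[1:], site.ref_base)
    else:
        key = VariantKey(site.chrom, site.pos, site.ref_base, allele)
    if genome is not None and site.chrom in genome:
        key = left_align_key(key, genome[site.chrom])
    return key


def call_variants(
    sites: Iterable[PileupSite],
    config: PipelineConfig,
    genome: dict[str, str] | None = None,
) -> list[VariantCall]:
    """Call variants for one pool: depth gate, fraction gate, then joint BH.

    Sites must come from a single pool and be sorted by (chrom, pos).  When
    ``genome`` is supplied indel keys are left-aligned against it.  Output
    is sorted by key.
    """
    candidates: list[tuple[PileupSite, str, int]] = []
    prev: tuple[str, int] | None = None
    pool: str | None = None
    for site in sites:
        if pool is None:
            pool = site.pool_id
        elif site.pool_id != pool:
            raise ValueError(f"mixed pool_ids: {pool!r} and {site.pool_id!r}")
        cur = (site.chrom, site.pos)
        if prev is not None and cur[0] == prev[0] and cur[1] < prev[1]:
            raise ValueError(f"sites not sorted by position at {site.chrom}:{site.pos}")
        prev = cur
        if site.depth <= config.min_depth_exclusive:
            continue
        modal = _modal_alt(site)
        if modal is None:
            continue
        allele, count = modal
        if count / site.depth < config.het_fraction_min:
            continue
        candidates.append((site, allele, count))

    pvals = [
        site_pvalue(count, site.depth, config.base_error_rate)
        for site, _, count in candidates
    ]
    flags = bh_fdr(pvals, config.fdr_q)

    calls: list[VariantCall] = []
    for (site, allele, count), p, keep in zip(candidates, pvals, flags):
        if not keep:
            continue
        key = _allele_to_key(site, allele, genome)
        calls.append(
            VariantCall(
                key=key,
                var_type=var_type(key),
                pool_id=site.pool_id,
                depth=site.depth,
                alt_count=count,
                zygosity_class=classify_zygosity(count / site.depth, config),
                p_value=p,
                passed_fdr=True,
            )
        )
    calls.sort(key=lambda c: c.key)
    return calls
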