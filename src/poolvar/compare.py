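"""Set algebra over the four pools (two breeds x high/low IgY).

Pools are named BY-H, BY-L (Beijing-You high/low) and WL-H, WL-L (White
Leghorn high/low).  Presence of a variant in a pool means the caller's
gates all passed there; absence of a call is treated as absence of the
variant.

Per-variant categories partition every presence-matrix row into seven
classes: {BY,WL}-only-{shared,high-specific,low-specific} and both-breeds.
Cross-breed common sets pair each breed's group-specific variants either by
identical key (same type) or by identical (chrom, pos, ref) with a
different alternate allele (different type).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .caller import VariantCall
from .formats import VariantKey, var_type

POOLS = ("BY-H", "BY-L", "WL-H", "WL-L")
BREEDS = {"BY": ("BY-H", "BY-L"), "WL": ("WL-H", "WL-L")}

CATEGORIES = (
    "BY-only-shared",
    "BY-only-high-specific",
    "BY-only-low-specific",
    "WL-only-shared",
    "WL-only-high-specific",
    "WL-only-low-specific",
    "both-breeds",
)


@dataclass(frozen=True)
class CommonPair:
    """A cross-breed common variant: one key per breed, possibly identical."""

    key_by: VariantKey
    key_wl: VariantKey
    match_type: str  # same-type | different-type

    def __post_init__(self) -> None:
        if self.match_type not in {"same-type", "different-type"}:
            raise ValueError(f"bad match_type {self.match_type}")


@dataclass
class PresenceMatrix:
    """Variant-key x pool presence table."""

    rows: dict[VariantKey, frozenset[str]]

    def pools_of(self, key: VariantKey) -> frozenset[str]:
        return self.rows[key]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ComparisonResult:
    categories: dict[VariantKey, str]
    common_high: list[CommonPair]
    common_low: list[CommonPair]


def build_matrix(call_sets: Mapping[str, Iterable[VariantCall]]) -> PresenceMatrix:
    """Union per-pool call lists into a presence matrix keyed by variant."""
    unknown = set(call_sets) - set(POOLS)
    if unknown:
        raise ValueError(f"unknown pool id(s): {sorted(unknown)}; expected {POOLS}")
    rows: dict[VariantKey, set[str]] = {}
    for pool, calls in call_sets.items():
        seen: set[VariantKey] = set()
        for call in calls:
            if call.key in seen:
                raise ValueError(f"duplicate key {call.key} within pool {pool}")
            seen.add(call.key)
            rows.setdefault(call.key, set()).add(pool)
    return PresenceMatrix({k: frozenset(v) for k, v in rows.items()})


def categorize(pools: frozenset[str]) -> str:
    """Seven-way category of one presence row."""
    if not pools:
        raise ValueError("presence row with no pools")
    in_by = bool(pools & set(BREEDS["BY"]))
    in_wl = bool(pools & set(BREEDS["WL"]))
    if in_by and in_wl:
        return "both-breeds"
    breed = "BY" if in_by else "WL"
    high, low = BREEDS[breed]
    if high in pools and low in pools:
        return f"{breed}-only-shared"
    if high in pools:
        return f"{breed}-only-high-specific"
    return f"{breed}-only-low-specific"


def breed_partition(matrix: PresenceMatrix) -> dict[VariantKey, str]:
    return {key: categorize(pools) for key, pools in matrix.rows.items()}


def group_specific_keys(matrix: PresenceMatrix, breed: str, group: str) -> set[VariantKey]:
    """Keys present in the breed's ``group`` pool and absent from its other
    pool (the within-breed high/low contrast), regardless of the other breed."""
    high, low = BREEDS[breed]
    want, avoid = (high, low) if group == "high" else (low, high)
    return {
        key for key, pools in matrix.rows.items() if want in pools and avoid not in pools
    }


def _pair_group(by_keys: set[VariantKey], wl_keys: set[VariantKey]) -> list[CommonPair]:
    pairs: list[CommonPair] = []
    same = sorted(by_keys & wl_keys)
    for key in same:
        pairs.append(CommonPair(key, key, "same-type"))
    rem_by = sorted(by_keys - set(same))
    rem_wl = wl_keys - set(same)
    # greedy position matching in sorted order: same (chrom,pos,ref), alt differs
    wl_by_site: dict[tuple[str, int, str], list[VariantKey]] = {}
    for k in sorted(rem_wl):
        wl_by_site.setdefault((k.chrom, k.pos, k.ref), []).append(k)
    for k in rem_by:
        bucket = wl_by_site.get((k.chrom, k.pos, k.ref))
        if bucket:
            partner = bucket.pop(0)
            pairs.append(CommonPair(k, partner, "different-type"))
    pairs.sort(key=lambda p: (p.key_by.chrom, p.key_by.pos, p.key_by.ref, p.key_by.alt))
    return pairs


def cross_breed_common(matrix: PresenceMatrix) -> ComparisonResult:
    """Full comparison: per-variant categories plus cross-breed common-high
    and common-low sets with same-/different-type pairing."""
    categories = breed_partition(matrix)
    common = {}
    for group in ("high", "low"):
        by_spec = group_specific_keys(matrix, "BY", group)
        wl_spec = group_specific_keys(matrix, "WL", group)
        common[group] = _pair_group(by_spec, wl_spec)
    return ComparisonResult(categories, common["high"], common["low"])


def indel_match(key_a: VariantKey, key_b: VariantKey, window: int) -> str:
    """Match two Indel keys: identical -> same-type; within ``window`` bp on
    the same chromosome (different allele or position) -> different-type;
    otherwise no-match."""
    for k in (key_a, key_b):
        if var_type(k) == "SNP":
            raise ValueError(f"{k}: indel_match expects Indel keys")
    if key_a.chrom != key_b.chrom:
        return "no-match"
    if key_a == key_b:
        return "same-type"
    if abs(key_a.pos - key_b.pos) <= window:
        return "different-type"
    return "no-match"


def category_counts(categories: Mapping[VariantKey, str]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for cat in categories.values():
        counts[cat] += 1
    return counts
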