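"""Report surfaces: group phenotype statistics, SNP/Indel distribution
tables with percentages, non-synonymous/promoter count tables, gene-level
common-variant maps, and Sanger-validation consistency accounting.

All percentages are rounded half-up to 1 decimal; means/s.d. to 2 decimals;
fold changes to 1 decimal, matching report-table conventions.

Union-level zygosity rule (documented in output headers): a variant that is
pool-homozygous in every pool containing it counts as homozygous, otherwise
heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd

from .annotate import AnnotationRecord
from .caller import VariantCall
from .compare import ComparisonResult, CommonPair
from .config import round_half_up
from .formats import VariantKey


@dataclass(frozen=True)
class GroupStats:
    breed: str
    group: str  # high | low | all
    n: int
    mean: float  # ng/uL
    sd: float  # ng/uL


@dataclass
class DistributionTable:
    """Ordered (label, count, percent) rows against a shared total."""

    rows: list[tuple[str, int, float]]
    total: int

    def percent_of(self, label: str) -> float:
        for lab, _, pct in self.rows:
            if lab == label:
                return pct
        raise KeyError(label)

    def count_of(self, label: str) -> int:
        for lab, cnt, _ in self.rows:
            if lab == label:
                return cnt
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "count", "percent"]).assign(
            total=self.total
        )


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1) if total else 0.0


def group_stats(phenotypes: pd.DataFrame) -> list[GroupStats]:
    """Per-(breed, group) and per-breed IgY mean +/- sample s.d.

    ``phenotypes`` columns: bird_id, breed, group (high/low), igy_ng_ul.
    Groups with no birds are omitted with a warning.
    """
    out: list[GroupStats] = []
    for breed, df_b in phenotypes.groupby("breed", sort=True):
        groups = [("all", df_b)] + [
            (g, df_b[df_b["group"] == g]) for g in ("high", "low")
        ]
        for gname, df in groups:
            if len(df) == 0:
                warnings.warn(f"group {breed}/{gname} has no birds; omitted")
                continue
            vals = df["igy_ng_ul"].to_numpy(dtype=float)
            mean = round_half_up(float(vals.mean()), 2)
            sd = round_half_up(float(pd.Series(vals).std(ddof=1)) if len(vals) > 1 else 0.0, 2)
            out.append(GroupStats(str(breed), gname, len(df), mean, sd))
    return out


def fold_change(high_mean: float, low_mean: float) -> float:
    """High/low group mean ratio, 1 decimal, half-up."""
    if low_mean <= 0:
        raise ValueError(f"low_mean must be > 0, got {low_mean}")
    return round_half_up(high_mean / low_mean, 1)


def _union_zygosity(calls_by_pool: Mapping[str, Sequence[VariantCall]]) -> dict[VariantKey, str]:
    zyg: dict[VariantKey, set[str]] = {}
    for calls in calls_by_pool.values():
        for c in calls:
            zyg.setdefault(c.key, set()).add(c.zygosity_class)
    return {
        k: ("homozygous" if classes == {"pool-homozygous"} else "heterozygous")
        for k, classes in zyg.items()
    }


def snp_distribution(
    calls_by_pool: Mapping[str, Sequence[VariantCall]],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> DistributionTable:
    """SNP distribution across genomic components (union over pools).

    Columns: homozygous, heterozygous, non-synonymous, synonymous, gene,
    mRNA; percents against the total unique SNP count.
    """
    zyg = _union_zygosity(calls_by_pool)
    snp_keys = sorted(k for k in zyg if len(k.ref) == 1 and len(k.alt) == 1)
    total = len(snp_keys)
    counts = {
        "homozygous": sum(zyg[k] == "homozygous" for k in snp_keys),
        "heterozygous": sum(zyg[k] == "heterozygous" for k in snp_keys),
        "non-synonymous": sum(
            annotations[k].effect == "non-synonymous" for k in snp_keys if k in annotations
        ),
        "synonymous": sum(
            annotations[k].effect == "synonymous" for k in snp_keys if k in annotations
        ),
        "gene": sum(annotations[k].in_gene for k in snp_keys if k in annotations),
        "mRNA": sum(annotations[k].in_mrna for k in snp_keys if k in annotations),
    }
    rows = [(lab, cnt, _pct(cnt, total)) for lab, cnt in counts.items()]
    return DistributionTable(rows, total)


def indel_distribution(
    calls_by_pool: Mapping[str, Sequence[VariantCall]],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> DistributionTable:
    """Indel distribution: insertion, deletion, CDS, UTR, mRNA."""
    keys = sorted(
        {c.key for calls in calls_by_pool.values() for c in calls if c.var_type != "SNP"}
    )
    total = len(keys)

    def comp_hit(k: VariantKey, comps: set[str]) -> bool:
        rec = annotations.get(k)
        return rec is not None and any(comp in comps for _, comp in rec.hits)

    counts = {
        "insertion": sum(len(k.alt) > len(k.ref) for k in keys),
        "deletion": sum(len(k.ref) > len(k.alt) for k in keys),
        "CDS": sum(comp_hit(k, {"CDS"}) for k in keys),
        "UTR": sum(comp_hit(k, {"utr5", "utr3"}) for k in keys),
        "mRNA": sum(annotations[k].in_mrna for k in keys if k in annotations),
    }
    rows = [(lab, cnt, _pct(cnt, total)) for lab, cnt in counts.items()]
    return DistributionTable(rows, total)


def distribution_from_counts(counts: Mapping[str, int], total: int) -> DistributionTable:
    """Build a DistributionTable directly from published/count cells."""
    rows = [(lab, cnt, _pct(cnt, total)) for lab, cnt in counts.items()]
    return DistributionTable(rows, total)


def nonsyn_promoter_counts(
    comparison: ComparisonResult,
    matrix_rows: Mapping[VariantKey, frozenset[str]],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> pd.DataFrame:
    """Count table of non-synonymous CDS SNPs and promoter SNPs per
    group-specific class (per breed high/low, plus cross-breed common)."""
    from .compare import PresenceMatrix, group_specific_keys

    matrix = PresenceMatrix(dict(matrix_rows))

    def tally(keys: Iterable[VariantKey]) -> tuple[int, int]:
        cds = prom = 0
        for k in keys:
            rec = annotations.get(k)
            if rec is None or not (len(k.ref) == 1 and len(k.alt) == 1):
                continue
            if rec.effect == "non-synonymous":
                cds += 1
            if any(comp == "promoter" for _, comp in rec.hits):
                prom += 1
        return cds, prom

    rows = []
    for breed in ("WL", "BY"):
        for group in ("high", "low"):
            keys = group_specific_keys(matrix, breed, group)
            cds, prom = tally(keys)
            rows.append((f"{breed} {group} IgY group", cds, prom))
    for group, pairs in (("high", comparison.common_high), ("low", comparison.common_low)):
        keys = {p.key_by for p in pairs} | {p.key_wl for p in pairs}
        cds, prom = tally(keys)
        rows.append((f"Common in {group} IgY groups", cds, prom))
    return pd.DataFrame(rows, columns=["class", "non_synonymous_cds", "proximal_promoter"])


def common_gene_map(
    comparison: ComparisonResult,
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> pd.DataFrame:
    """Gene-level map of cross-breed common variants.

    One row per (group, gene, component) for SNPs in promoter or CDS, and
    one row per common Indel listing every gene/component it touches (a
    single Indel spanning two genes yields one row with both listed).
    """
    rows = []
    for group, pairs in (("high", comparison.common_high), ("low", comparison.common_low)):
        for pair in pairs:
            for key in sorted({pair.key_by, pair.key_wl}):
                rec = annotations.get(key)
                if rec is None:
                    continue
                is_snp = len(key.ref) == 1 and len(key.alt) == 1
                if is_snp:
                    for gene_id, comp in rec.hits:
                        if comp in {"promoter", "CDS"}:
                            rows.append(
                                (group, "SNP", str(key), "", gene_id,
                                 "proximal promoter" if comp == "promoter" else "CDS")
                            )
                else:
                    seq = key.ref[1:] if len(key.ref) > len(key.alt) else key.alt[1:]
                    genes = " / ".join(g for g, _ in rec.hits) or "intergenic"
                    comps = " / ".join(
                        {"utr3": "3'UTR", "utr5": "5'UTR"}.get(c, c) for _, c in rec.hits
                    )
                    rows.append((group, rec.indel_class, str(key), seq, genes, comps))
    return pd.DataFrame(
        rows, columns=["igy_group", "type", "variant", "sequence", "genes", "components"]
    ).drop_duplicates(ignore_index=True)


def validation_rate(validation: pd.DataFrame) -> float:
    """Percent of SNP validation rows consistent with sequencing calls.

    ``validation`` columns: locus, type (SNP/Indel), consistent (bool).
    Indel rows are excluded from the denominator.  1 decimal, half-up.
    """
    snps = validation[validation["type"].str.upper() == "SNP"]
    if len(snps) == 0:
        raise ValueError("validation table has no SNP rows")
    return _pct(int(snps["consistent"].sum()), len(snps))


def write_tsv(df: pd.DataFrame, path: str | Path, header_note: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False)
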