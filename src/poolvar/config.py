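"""Pipeline configuration and shared genomic coordinate types.

Coordinate convention: 1-based, fully closed intervals everywhere inside the
package (GFF3/pileup convention).  Conversion to 0-based half-open happens
only at the BED boundary in :mod:`poolvar.formats`.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable


class ConfigError(ValueError):
    """Raised for malformed config files or invariant violations."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed table values.

    Python's builtin round() is banker's rounding; report tables in this
    domain are conventionally rounded half-up (0.5 -> 1).
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds used by the calling/annotation/comparison pipeline.

    Parameters
    ----------
    min_depth_exclusive : int
        Sites must have read depth strictly greater than this to be
        considered (default 4, i.e. depth >= 5 passes).
    fdr_q : float
        Benjamini-Hochberg false-discovery-rate level for site calls.
    base_error_rate : float
        Per-base sequencing error probability used in the binomial null.
    het_fraction_min : float
        Minimum pool alt-allele fraction for any call (segregating gate).
    hom_fraction_min : float
        Alt fraction at or above which a pool call is classed as fixed
        ("pool-homozygous").
    promoter_length : int
        Proximal promoter extent: this many bp immediately upstream of the
        transcription start site (TSS), TSS itself excluded.
    indel_match_window : int
        Window (bp) within which two Indels at different positions count as
        a same-region, different-type pair.
    random_seed : int
        Seed threaded through simulation entry points.
    """

    min_depth_exclusive: int = 4
    fdr_q: float = 0.01
    base_error_rate: float = 0.01
    het_fraction_min: float = 0.2
    hom_fraction_min: float = 0.8
    promoter_length: int = 2000
    indel_match_window: int = 10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ConfigError(f"fdr_q must be in (0,1), got {self.fdr_q}")
        if not (0 < self.base_error_rate < 0.5):
            raise ConfigError(
                f"base_error_rate must be in (0,0.5), got {self.base_error_rate}"
            )
        if not (0 < self.het_fraction_min <= self.hom_fraction_min <= 1):
            raise ConfigError(
                "require 0 < het_fraction_min <= hom_fraction_min <= 1, got "
                f"het={self.het_fraction_min} hom={self.hom_fraction_min}"
            )
        if self.min_depth_exclusive < 0:
            raise ConfigError(
                f"min_depth_exclusive must be >= 0, got {self.min_depth_exclusive}"
            )
        if self.promoter_length <= 0:
            raise ConfigError(
                f"promoter_length must be > 0, got {self.promoter_length}"
            )

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in dc_fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


_INT_FIELDS = {"min_depth_exclusive", "promoter_length", "indel_match_window", "random_seed"}
_FLOAT_FIELDS = {"fdr_q", "base_error_rate", "het_fraction_min", "hom_fraction_min"}


def parse_flat_keyvalue(text: str) -> dict[str, str]:
    """Parse the flat ``key: value`` dialect used for configs and designs.

    Blank lines and ``#`` comments are ignored.  Raises ConfigError naming
    the offending line number on malformed input.
    """
    out: dict[str, str] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigError(f"line {ln}: expected 'key: value', got {raw!r}")
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if not key:
            raise ConfigError(f"line {ln}: empty key")
        if key in out:
            raise ConfigError(f"line {ln}: duplicate key {key!r}")
        out[key] = val
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a flat key->value file.

    Missing keys take their defaults; unknown keys are rejected.
    """
    mapping = parse_flat_keyvalue(Path(path).read_text())
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs: dict[str, object] = {}
    for key, val in mapping.items():
        try:
            kwargs[key] = int(val) if key in _INT_FIELDS else float(val)
        except ValueError as exc:
            raise ConfigError(f"field {key}: cannot parse {val!r}") from exc
    return PipelineConfig(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def region_length_mb(region: GenomicInterval) -> float:
    """Span of a capture region in megabases, 2 decimals, half-up.

    Deliberately (end - start)/1e6, not +1: this is the convention the
    published capture-region table follows for every row.
    """
    return round_half_up((region.end - region.start) / 1e6, 2)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware single-transcript gene model.

    Exons are stored in transcription order (5'->3' on the gene's strand);
    CDS segments and UTR intervals are sub-intervals of the exons.  The TSS
    is the transcription-start coordinate: min start on '+', max end on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_segments: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: gene strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model requires >=1 exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        expected = tuple(genomic if self.strand == "+" else genomic[::-1])
        if tuple(self.exons) != expected:
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        for label, segs in (("CDS", self.cds_segments), ("utr5", self.utr5), ("utr3", self.utr3)):
            for seg in segs:
                if not any(e.start <= seg.start and seg.end <= e.end for e in self.exons):
                    raise ValueError(
                        f"{self.gene_id}: {label} segment {seg.start}-{seg.end} outside exons"
                    )

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return min(e.start for e in self.exons)
        return max(e.end for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Gene body: first to last exonic base."""
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        genomic = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(genomic, genomic[1:]):
            out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand))
        return tuple(out)

    def cds_length(self) -> int:
        return sum(s.length for s in self.cds_segments)


def sort_intervals_tx_order(ivs: Iterable[GenomicInterval], strand: str) -> tuple[GenomicInterval, ...]:
    """Sort intervals into transcription order for the given strand."""
    return tuple(sorted(ivs, key=lambda i: i.start, reverse=(strand == "-")))
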