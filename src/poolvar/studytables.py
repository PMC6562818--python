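"""Published summary values from the divergent-IgY capture-sequencing
experiment this pipeline models.

These are report-level inputs (group statistics, capture-chip regions,
distribution count cells, Sanger validation outcomes); the raw sequencing
data behind them was never released, so the pipeline's statistics are
exercised on these printed cells and on synthetic data.
"""

from __future__ import annotations

from .config import GenomicInterval

# group IgY statistics (ng/uL): breed -> {group: (n, mean, sd)}
GROUP_IGY = {
    "WL": {"all": (527, 679.9, 768.17), "high": (40, 1501.70, 1678.05), "low": (40, 293.91, 58.29)},
    "BY": {"all": (726, 628.2, 923.987), "high": (40, 1888.84, 1189.55), "low": (40, 302.55, 24.91)},
}

# capture-chip regions: (chrom, start, end, phenotype)
CAPTURE_REGIONS = [
    ("11", 4_412_041, 5_661_311, "IgY level"),
    ("11", 13_531_246, 14_463_528, "antibody responses to SRBC"),
    ("16", 1, 535_270, "IgY level"),
    ("19", 8_974_480, 9_730_805, "antibody responses to SRBC"),
]


def capture_intervals() -> list[GenomicInterval]:
    return [GenomicInterval(c, s, e) for c, s, e, _ in CAPTURE_REGIONS]


# SNP distribution count cells (total 35,154 unique SNPs across pools)
SNP_TOTAL = 35_154
SNP_COUNTS = {
    "homozygous": 28_862,
    "heterozygous": 6_292,
    "non-synonymous": 1_045,
    "synonymous": 2_190,
    "gene": 18_332,
    "mRNA": 22_327,
}

# Indel distribution count cells (total 23,309 unique Indels)
INDEL_TOTAL = 23_309
INDEL_COUNTS = {
    "insertion": 11_211,
    "deletion": 12_098,
    "CDS": 1_051,
    "UTR": 796,
    "mRNA": 11_949,
}

# Sanger validation outcomes: (locus, type, consistent with sequencing)
VALIDATION_ROWS = [
    ("Chr16:213135", "SNP", True),
    ("Chr16:213142", "SNP", True),
    ("Chr16:213221", "SNP", True),
    ("Chr16:213160", "SNP", False),
    ("Chr16:61196", "SNP", True),
    ("Chr16:61211", "SNP", True),
    ("Chr11:4464202", "SNP", True),
    ("Chr11:4478491", "SNP", True),
    ("Chr11:4478592", "SNP", True),
    ("Chr11:4478634", "SNP", True),
    ("Chr11:4480688", "SNP", True),
    ("Chr11:4480721", "SNP", True),
    ("Chr11:4479104", "SNP", True),
    ("Chr11:4479176", "SNP", True),
    ("Chr11:4479218", "SNP", True),
    ("Chr11:4479254", "SNP", True),
    ("Chr11:4480840", "SNP", True),
    ("Chr11:4480934", "SNP", True),
    ("Chr11:4480961", "SNP", True),
    ("Chr11:4480971", "SNP", True),
    ("Chr11:4481057", "SNP", True),
    ("Chr11:4481115", "SNP", True),
    ("Chr11:4478592b", "SNP", False),
    ("Chr11:4478634b", "SNP", False),
    ("Chr16:74016-74024", "Indel", True),
]

# the cross-breed common deletion in the overlapping 3'UTR/intron region
BF1_DELETION_SEQ = "CCACTGCCA"
BF1_DELETION_ANCHOR = ("16", 74_015)  # VCF-style anchor base before the deleted run
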