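#!/usr/bin/env python
"""Stage 4: four-pool set algebra.

Builds the variant x pool presence matrix, partitions it into the seven
breed/group categories, extracts cross-breed common-high and common-low
sets (same-type vs same-position-different-allele pairs), and scores
recovery of the planted truth.  Writes comparison.tsv and venn_counts.tsv.
"""

from pathlib import Path

import pandas as pd

from poolvar.compare import POOLS, build_matrix, category_counts, cross_breed_common
from poolvar.formats import read_vcf
from poolvar.simulate import read_truth_tsv, score_recovery

RUN = Path(__file__).resolve().parents[1] / "results" / "synthetic_run"


def main() -> None:
    if not (RUN / "calls_BY-H.vcf").exists():
        raise SystemExit("run analysis/02_call_variants.py first")
    calls_by_pool = {p: read_vcf(RUN / f"calls_{p}.vcf") for p in POOLS}
    matrix = build_matrix(calls_by_pool)
    result = cross_breed_common(matrix)

    pd.DataFrame(
        [(str(k), ",".join(sorted(matrix.rows[k])), c) for k, c in sorted(result.categories.items())],
        columns=["variant", "pools", "category"],
    ).to_csv(RUN / "comparison.tsv", sep="\t", index=False)

    counts = category_counts(result.categories)
    venn = pd.DataFrame(sorted(counts.items()), columns=["category", "count"])
    venn.to_csv(RUN / "venn_counts.tsv", sep="\t", index=False)

    truth = read_truth_tsv(RUN / "truth.tsv")
    precision, recall = score_recovery(truth, matrix, result)

    print(f"{len(matrix.rows)} variants across 4 pools")
    for cat, n in sorted(counts.items()):
        print(f"  {cat:>24}: {n}")
    same_h = sum(p.match_type == "same-type" for p in result.common_high)
    diff_h = len(result.common_high) - same_h
    same_l = sum(p.match_type == "same-type" for p in result.common_low)
    print(f"  common-high pairs: {len(result.common_high)} ({same_h} same-type, {diff_h} different-type)")
    print(f"  common-low pairs: {len(result.common_low)} ({same_l} same-type)")
    print(f"truth recovery: precision {precision:.3f}, recall {recall:.3f}")


if __name__ == "__main__":
    main()
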