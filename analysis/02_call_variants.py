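#!/usr/bin/env python
"""Stage 2: per-pool variant calling.

Applies the three calling gates (depth > 4, alt fraction >= 0.2,
Benjamini-Hochberg FDR < 0.01 over binomial-tail p-values) to each pool's
pileup and writes one VCF per pool under results/synthetic_run/.
"""

from pathlib import Path

from poolvar.compare import POOLS
from poolvar.config import PipelineConfig
from poolvar.formats import read_fasta
from poolvar.pipeline import call_pool_file

RUN = Path(__file__).resolve().parents[1] / "results" / "synthetic_run"


def main() -> None:
    if not (RUN / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    config = PipelineConfig()
    genome = read_fasta(RUN / "genome.fa")
    for pool in POOLS:
        calls = call_pool_file(
            RUN / f"pileup_{pool}.txt", pool, config, genome, RUN / f"calls_{pool}.vcf"
        )
        n_hom = sum(c.zygosity_class == "pool-homozygous" for c in calls)
        print(f"{pool}: {len(calls)} calls "
              f"({sum(c.var_type == 'SNP' for c in calls)} SNPs, "
              f"{len(calls) - sum(c.var_type == 'SNP' for c in calls)} Indels; "
              f"{n_hom} pool-fixed)")


if __name__ == "__main__":
    main()
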