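#!/usr/bin/env python
"""Stage 3: annotate called variants against the gene models.

Each variant is mapped to the most specific component of every gene it
touches (CDS > UTR > intron > 2-kb proximal promoter); CDS SNPs get a
synonymous/non-synonymous call by codon substitution.  Writes
results/synthetic_run/annotations.tsv and prints the component spectrum.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from poolvar.annotate import annotate_calls
from poolvar.compare import POOLS
from poolvar.config import PipelineConfig
from poolvar.formats import read_fasta, read_gff3, read_vcf

RUN = Path(__file__).resolve().parents[1] / "results" / "synthetic_run"


def main() -> None:
    if not (RUN / "calls_BY-H.vcf").exists():
        raise SystemExit("run analysis/02_call_variants.py first")
    config = PipelineConfig()
    genome = read_fasta(RUN / "genome.fa")
    models = read_gff3(RUN / "genes.gff3")
    keys = sorted({c.key for p in POOLS for c in read_vcf(RUN / f"calls_{p}.vcf")})
    ann = annotate_calls(keys, models, genome, config)

    rows = [
        (str(k), ";".join(f"{g}:{c}" for g, c in r.hits) or "intergenic",
         r.effect, r.indel_class, r.in_mrna, r.in_gene)
        for k, r in ann.items()
    ]
    pd.DataFrame(
        rows, columns=["variant", "gene_hits", "effect", "indel_class", "in_mrna", "in_gene"]
    ).to_csv(RUN / "annotations.tsv", sep="\t", index=False)

    comp = Counter(c for r in ann.values() for _, c in r.hits)
    eff = Counter(r.effect for r in ann.values())
    dual = sum(len({g for g, _ in r.hits}) > 1 for r in ann.values())
    print(f"{len(keys)} unique variants annotated")
    print(f"  components: {dict(comp)}")
    print(f"  effects: {dict(eff)}")
    print(f"  variants hitting >1 gene (overlap support): {dual}")


if __name__ == "__main__":
    main()
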