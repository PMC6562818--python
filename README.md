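# poolvar

Pooled capture-sequencing variant analysis for divergently selected chicken
lines.

Serum immunoglobulin Y (IgY) is the dominant antibody of birds. Comparing
White Leghorn (WL) and Beijing-You (BY) chickens with extreme high and low
IgY levels, targeted capture sequencing of candidate regions (chiefly the
MHC-B region on microchromosome GGA16 plus GWAS-implicated intervals on
GGA11/GGA19) yields per-pool read pileups — DNA is pooled from 10 birds per
pool, so only pool-level allele fractions are observable. `poolvar`
implements the full downstream analysis for such a design:

1. **Pool calling.** From samtools-style text pileups, each site's modal
   non-reference allele is tested against a sequencing-error null: the
   p-value is the binomial upper tail P[X ≥ k | X ~ Bin(n, ε)] with depth
   n, alt count k and base-error rate ε = 0.01. Calls require coverage
   n > 4, alt fraction ≥ 0.2, and Benjamini–Hochberg FDR < 0.01 applied
   jointly over all candidate sites of the pool. Pool-level zygosity is a
   fraction heuristic: alt fraction ≥ 0.8 ⇒ fixed ("pool-homozygous").
2. **Annotation.** Variants map to the most specific component per
   overlapping gene (CDS > UTR > intron > proximal promoter, the promoter
   being the 2000 bp immediately upstream of the TSS, strand-aware). CDS
   SNPs get synonymous/non-synonymous calls by codon substitution under
   the standard genetic code; all hit genes are kept, so a deletion in one
   gene's 3′UTR and another's intron is reported under both.
3. **Four-pool set algebra.** A variant × pool presence matrix over
   {BY-H, BY-L, WL-H, WL-L} is partitioned into breed-specific (shared /
   high-specific / low-specific) and both-breeds classes; cross-breed
   common-high/common-low sets pair each breed's group-specific variants
   by identical key ("same type") or identical position with a different
   alternate allele ("different type").
4. **Reports.** Group IgY statistics with fold changes, SNP/Indel
   component distributions with percentages, non-synonymous/promoter count
   tables, gene-level common-variant maps and Sanger-validation
   consistency rates.

A first-class synthetic-data module (`poolvar.simulate`) generates genomes,
gene models (including a 3′UTR-in-intron overlapping gene pair, the
TAP1/BF1 configuration), planted truth sets spanning every category, and
noisy pool pileups — so the whole pipeline runs and is tested with no
external data.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_call_variants.py
python analysis/04_compare_groups.py
```

prints, for the default design (2 × 35 kb chromosomes, 10 genes, 210
planted variants, depth ~30, noise-free):

```
BY-H: 80 calls (56 SNPs, 24 Indels; 37 pool-fixed)
...
210 variants across 4 pools
     BY-only-high-specific: 25
      BY-only-low-specific: 25
            BY-only-shared: 30
     WL-only-high-specific: 25
      WL-only-low-specific: 25
            WL-only-shared: 30
               both-breeds: 50
  common-high pairs: 30 (25 same-type, 5 different-type)
  common-low pairs: 30 (25 same-type)
truth recovery: precision 1.000, recall 1.000
```

Each pool carries exactly the 80 planted variants it should (e.g. BY-H =
30 BY-shared + 20 BY-high-only + 25 common-high + 5 same-position pairs),
every presence-matrix row lands in its intended category, and the five
planted same-position-different-allele pairs surface as different-type
common-high pairs — the caller, comparator and truth bookkeeping agree
exactly in the noise-free regime. `analysis/03_annotate_variants.py` and
`analysis/05_summarize_tables.py` add component annotation and the report
tables (written under `results/synthetic_run/`).

The same pipeline is exposed as a CLI:

```bash
poolvar run-all --seed 7 --out-dir out/   # simulate -> call -> annotate -> compare -> report
poolvar call pileup_BY-H.txt --pool-id BY-H --genome genome.fa
```

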