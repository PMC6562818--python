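# Methods

## Study design being modeled

Two chicken breeds (White Leghorn, Beijing-You) divided into high- and
low-IgY groups; DNA pooled from 10 birds per pool and capture-sequenced
over candidate regions. Four pools — BY-H, BY-L, WL-H, WL-L — are the unit
of observation: with 10 diploid birds per pool, the true alt-allele
fraction in a pool is a multiple of 1/20, and individual genotypes are not
observable. The analysis asks which variants are breed-specific, which are
specific to the high or low group within a breed, and which are common to
both breeds' high (or low) groups, including pairs that share a position
but carry different alternate alleles.

## Coordinates and variant keys

All internal coordinates are 1-based, fully closed (GFF3/pileup
convention); conversion to 0-based half-open happens only at the BED
boundary. A variant is identified by the canonical key
(chrom, pos, ref, alt), VCF-anchored for indels (deletion =
anchor+deleted vs anchor, insertion = anchor vs anchor+inserted) and
left-aligned against the reference: shared trailing bases are trimmed and
the anchor shifted left while the flanking base matches, so the caller,
truth set and comparator agree on one representation per indel.
Capture-region lengths are reported as (end − start)/10⁶ rounded half-up
to 2 decimals — the convention the published region table follows — and
all printed percentages round half-up (the convention that reproduces the
published table cells).

## Calling model

Per site and pool, the candidate allele is the modal non-reference allele
(substitution or indel; ties broken lexicographically — pooled data at
depth ~30 rarely supports more than two alleles, and a deterministic
tie-break keeps runs reproducible). Three gates apply:

- **depth gate** — coverage strictly greater than `min_depth_exclusive`
  (default 4, i.e. ≥ 5 reads);
- **fraction gate** — alt fraction ≥ `het_fraction_min` (default 0.2, one
  carrier chromosome in a 10-bird pool at modest depth);
- **error-model gate** — binomial upper tail
  p = P[X ≥ k | X ~ Bin(n, ε)] with ε = `base_error_rate` (default 0.01),
  followed by Benjamini–Hochberg step-up at q = `fdr_q` (default 0.01)
  jointly over every candidate site of the pool.

The FDR procedure is applied per pool (each pool is one sequencing
experiment); the BH step-up itself is delegated to
`statsmodels.stats.multitest` and cross-checked in the tests against a
literal quadratic step-up enumeration. Zygosity is a pool-level
heuristic: alt fraction ≥ `hom_fraction_min` (default 0.8) means the
variant looks fixed in the pool ("pool-homozygous"), otherwise it is
segregating. These two fraction thresholds are operational choices, not
estimates; they are config-exposed.

Presence/absence semantics: a variant is "present" in a pool iff it passed
all gates there. A variant missing because of low local coverage is
indistinguishable from a true absence — there is no depth-aware missing
state. This is the main caveat when reading the set-algebra outputs.

## Annotation

Gene models are single-transcript: ordered exons, CDS segments and UTRs,
with the TSS implied by strand. The proximal promoter is the
`promoter_length` bp (default 2000) immediately upstream of the TSS,
strand-aware, TSS excluded, clipped at chromosome ends. A variant's
reference footprint (the span of its reference allele) is intersected with
every gene body or promoter it touches via an interval tree; per gene, the
single most specific component is reported with precedence
CDS > UTR > intron > promoter, and hits for all genes are kept — this
reproduces dual reporting for variants in overlapping genes (one gene's
3′UTR inside another's intron).

CDS SNP effect: the codon is located by cumulative CDS offset in
transcription order; on '−' strand genes both codon and alt base are
reverse-complemented; translation uses the standard nuclear code; stop
gain/loss counts as non-synonymous. Indels carry an insertion/deletion
class only — no frameshift or in-frame coding-effect prediction, since the
downstream tables only use indel position and class. "Gene" in the
distribution tables means the variant overlaps any gene body; "mRNA" means
it overlaps any exon (these columns are operationalized here and stated in
output headers). Union-level zygosity for the tables: homozygous iff
pool-fixed in every pool containing the variant.

## Set algebra

The presence matrix partitions into seven exhaustive, disjoint categories:
{BY,WL}-only-{shared, high-specific, low-specific} and both-breeds. For
cross-breed common sets, each breed's group-specific keys (present in its
high pool, absent from its low pool, the other breed unconstrained) are
matched across breeds: identical keys are same-type pairs; among the
remainder, keys sharing (chrom, pos, ref) with different alt are paired
greedily in sorted order as different-type, each key joining at most one
pair. Indel region matching (two indels "in the same region" but not
identical) uses a ±`indel_match_window` window, default 10 bp — the
underlying biological criterion is not standardized, so the window is
config-exposed.

## Synthetic data

`make_genome` draws i.i.d. uniform ACGT sequence (default two 35-kb
chromosomes — large enough to pack ten multi-exon genes with 2-kb
promoters while keeping a full four-pool simulation around a second).
`make_gene_models` packs three-exon genes on alternating strands with
frame-complete CDS and both UTRs, plus the requested number of constructed
overlapping pairs in which gene A's 3′UTR sits inside gene B's intron.
`plant_variants` places exact per-category counts (defaults: 30 shared +
20 high-only + 20 low-only per breed, 25 common-high, 25 common-low, 5 + 5
same-position-different-allele pairs = 210 records, ~70% SNPs, indel
lengths 1–9 bp) across CDS/promoter/UTR/intron/intergenic space with fixed
weights; intended pool fractions are multiples of 1/20 drawn from
[0.5, 1]. When an overlapping pair exists, one common-high 9-bp deletion
is forced into the shared 3′UTR∩intron region, mirroring the deletion that
anchors the gene-level report. Indels are planted left-aligned so truth
and caller keys coincide.

`simulate_pool_pileup` renders text pileups: depth ~ Poisson(`depth_mean`,
default 30); at truth sites carried by the pool, alt reads ~
Binomial(depth, f·(1−ε)); elsewhere errors ~ Binomial(depth, ε) spread
uniformly over the three non-reference bases; deletions are rendered with
the `-n<seq>` code on the anchor and `*` placeholders on the deleted
bases; SNP alt reads alternate case to exercise the parser's strand
folding.

What the generator does **not** emulate: read-level artifacts (mapping
bias, duplicates, base-quality structure), capture-efficiency variation,
linkage between variants, and indel-adjacent alignment noise. Passing
recovery tests therefore demonstrates the correctness of the calling/
comparison logic under the stated noise model, not robustness to real
alignment pathologies.

## Numerical and degenerate-input choices

- p-values are exact `scipy.stats.binom.sf` tails; stored in VCF INFO as
  `repr()` strings so round-trips are bit-exact (a float32 INFO field
  would underflow values like 10⁻⁶⁰).
- Rounding is half-up everywhere a table is printed (decimal module), not
  banker's rounding.
- Empty phenotype groups are omitted with a warning; zero-depth pileup
  sites are omitted; a pileup depth column disagreeing with the parsed
  symbols warns rather than errors (real pileups contain such lines).
- Genes whose TSS sits at the chromosome edge have no promoter interval.
- CDS length not divisible by 3 is an error naming the gene.

## Problem sizes

Default test/verification sizes: the noise-free recovery suite runs the
full pipeline on 5 seeds × 210 variants × 4 pools (70 kb genome); the
noisy false-discovery check runs 20 replicates of a 32-variant design on a
20-kb genome at ε = 0.01; oracle suites use 100 random ≤200-site caller
instances, 500 random BH vectors and ≥1000 random pileup grammar strings.
These sizes were chosen so the whole suite completes in well under a
minute while every category and code path is exercised; all scale linearly
if enlarged.

## Known limitations

- One transcript per gene; no splice-site classes; no frameshift effect
  prediction.
- Absence of a call is treated as absence of the variant (no coverage-
  aware missingness), so low-coverage pools can inflate "specific"
  categories on real data.
- The binomial/BH calling model is a defined, testable stand-in for a
  consensus-genotype caller; on real pileups its calls will differ from
  samtools' in borderline sites.
- The headline discovery counts of the motivating experiment derive from
  unreleased raw data and are not reproducible here; the pipeline
  reproduces the table arithmetic and the full analysis structure on
  synthetic data instead.
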