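"""End-to-end orchestration: simulate -> call -> annotate -> compare -> report.

Each stage reads and writes plain files (FASTA/GFF3/pileup/VCF/TSV) so
stages can be re-run independently; `run_end_to_end` chains them in one
process and returns the in-memory objects the tests and acceptance script
inspect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_calls
from .caller import VariantCall, call_variants
from .compare import POOLS, ComparisonResult, PresenceMatrix, build_matrix, cross_breed_common
from .config import PipelineConfig
from .formats import (
    iter_pileup,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
    write_vcf,
)
from .report import (
    fold_change,
    group_stats,
    indel_distribution,
    nonsyn_promoter_counts,
    snp_distribution,
    common_gene_map,
    write_tsv,
)
from .simulate import (
    TruthDesign,
    make_gene_models,
    make_genome,
    plant_variants,
    simulate_pool_pileup,
    score_recovery,
    write_truth_tsv,
)

# Synthetic phenotype generation: group-level IgY means/s.d. (ng/uL) chosen to
# mirror divergent selection magnitudes (roughly 5-6 fold high/low contrast).
PHENOTYPE_PARAMS = {
    ("WL", "high"): (1500.0, 1600.0),
    ("WL", "low"): (295.0, 60.0),
    ("BY", "high"): (1890.0, 1200.0),
    ("BY", "low"): (300.0, 25.0),
}


def simulate_phenotypes(seed: int, n_per_group: int = 40) -> pd.DataFrame:
    """Per-bird IgY values for the four (breed, group) cells.

    Values are truncated-normal draws (floored at 5 ng/uL) around the
    group-level parameters above; n defaults to 40 birds per group as in a
    four-repeats-of-ten pooling design.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (breed, group), (mean, sd) in PHENOTYPE_PARAMS.items():
        vals = np.maximum(rng.normal(mean, sd, n_per_group), 5.0)
        for i, v in enumerate(vals):
            rows.append((f"{breed}-{group}-{i:03d}", breed, group, round(float(v), 2)))
    return pd.DataFrame(rows, columns=["bird_id", "breed", "group", "igy_ng_ul"])


def simulate_dataset(
    design: TruthDesign, config: PipelineConfig, seed: int, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write genome, gene models, truth set, phenotypes and one
    pileup per pool.  Returns the paths keyed by artifact name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(design, seed)
    models = make_gene_models(genome, design, seed + 1)
    truth = plant_variants(genome, models, design, seed + 2)
    paths: dict[str, Path] = {
        "genome": out / "genome.fa",
        "genes": out / "genes.gff3",
        "truth": out / "truth.tsv",
        "design": out / "design.txt",
        "phenotypes": out / "phenotypes.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(models, paths["genes"])
    write_truth_tsv(truth, paths["truth"], seed)
    design.to_file(paths["design"])
    simulate_phenotypes(seed + 3).to_csv(paths["phenotypes"], sep="\t", index=False)
    for pool in POOLS:
        p = out / f"pileup_{pool}.txt"
        simulate_pool_pileup(genome, truth, pool, design, seed + 4, p)
        paths[f"pileup_{pool}"] = p
    return paths


def call_pool_file(
    pileup_path: str | Path,
    pool_id: str,
    config: PipelineConfig,
    genome: Mapping[str, str] | None = None,
    vcf_out: str | Path | None = None,
) -> list[VariantCall]:
    calls = call_variants(iter_pileup(pileup_path, pool_id), config, dict(genome) if genome else None)
    if vcf_out is not None:
        write_vcf(calls, vcf_out)
    return calls


def run_end_to_end(
    design: TruthDesign,
    config: PipelineConfig,
    seed: int,
    out_dir: str | Path,
    write_reports: bool = True,
) -> dict:
    """Full pipeline on one synthetic dataset.

    Returns a dict with genome, models, truth, per-pool calls, annotations,
    presence matrix, comparison result and recovery scores.
    """
    paths = simulate_dataset(design, config, seed, out_dir)
    genome = read_fasta(paths["genome"])
    models = read_gff3(paths["genes"])

    calls_by_pool: dict[str, list[VariantCall]] = {}
    for pool in POOLS:
        vcf = Path(out_dir) / f"calls_{pool}.vcf"
        calls_by_pool[pool] = call_pool_file(
            paths[f"pileup_{pool}"], pool, config, genome, vcf
        )
        paths[f"vcf_{pool}"] = vcf

    matrix = build_matrix(calls_by_pool)
    result = cross_breed_common(matrix)
    keys = sorted(matrix.rows)
    annotations = annotate_calls(keys, models, genome, config)

    from .simulate import read_truth_tsv

    truth = read_truth_tsv(paths["truth"])
    precision, recall = score_recovery(truth, matrix, result)

    out = {
        "paths": paths,
        "genome": genome,
        "models": models,
        "truth": truth,
        "calls_by_pool": calls_by_pool,
        "matrix": matrix,
        "result": result,
        "annotations": annotations,
        "precision": precision,
        "recall": recall,
    }
    if write_reports:
        write_report_tables(out, config, Path(out_dir))
        _write_manifest(out, config, seed, Path(out_dir))
    return out


def write_report_tables(state: dict, config: PipelineConfig, out_dir: Path) -> None:
    """Emit the summary-table surfaces for one pipeline run."""
    out_dir.mkdir(parents=True, exist_ok=True)
    phen = pd.read_csv(state["paths"]["phenotypes"], sep="\t")
    stats = group_stats(phen)
    rows = []
    by_cell = {(s.breed, s.group): s for s in stats}
    for breed in sorted({s.breed for s in stats}):
        hi, lo = by_cell.get((breed, "high")), by_cell.get((breed, "low"))
        fc = fold_change(hi.mean, lo.mean) if hi and lo else float("nan")
        for s in (by_cell.get((breed, "all")), hi, lo):
            if s:
                rows.append((s.breed, s.group, s.n, s.mean, s.sd, fc))
    write_tsv(
        pd.DataFrame(rows, columns=["breed", "group", "n", "mean_ng_ul", "sd_ng_ul", "fold_change"]),
        out_dir / "table1_group_stats.tsv",
        "group IgY statistics; fold change = high mean / low mean",
    )

    ann = state["annotations"]
    snp_tab = snp_distribution(state["calls_by_pool"], ann)
    write_tsv(
        snp_tab.to_frame(), out_dir / "table3_snp_distribution.tsv",
        "union across pools; homozygous = pool-fixed in every pool carrying the variant; "
        "gene = overlaps any gene body; mRNA = overlaps any exon",
    )
    indel_tab = indel_distribution(state["calls_by_pool"], ann)
    write_tsv(
        indel_tab.to_frame(), out_dir / "table4_indel_distribution.tsv",
        "union across pools; CDS/UTR/mRNA by reference-footprint overlap",
    )
    write_tsv(
        nonsyn_promoter_counts(state["result"], state["matrix"].rows, ann),
        out_dir / "table7_nonsyn_counts.tsv",
        "non-synonymous CDS SNPs and proximal-promoter SNPs per group-specific class",
    )
    write_tsv(
        common_gene_map(state["result"], ann),
        out_dir / "table8_gene_map.tsv",
        "genes carrying cross-breed common variants in promoter or CDS",
    )
    # Venn-style category counts (set-partition surfaces)
    from .compare import category_counts

    counts = category_counts(state["result"].categories)
    venn = pd.DataFrame(sorted(counts.items()), columns=["category", "count"])
    venn.loc[len(venn)] = ["common-high-pairs", len(state["result"].common_high)]
    venn.loc[len(venn)] = ["common-low-pairs", len(state["result"].common_low)]
    write_tsv(venn, out_dir / "venn_counts.tsv", "presence-matrix partition counts")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(state: dict, config: PipelineConfig, seed: int, out_dir: Path) -> None:
    manifest = {
        "tool": "poolvar",
        "version": __version__,
        "seed": seed,
        "config": asdict(config),
        "inputs": {
            name: _digest(p)
            for name, p in state["paths"].items()
            if Path(p).exists()
        },
        "counts": {
            "truth_records": len(state["truth"]),
            "matrix_rows": len(state["matrix"].rows),
            **{f"calls_{p}": len(c) for p, c in state["calls_by_pool"].items()},
        },
        "recovery": {"precision": state["precision"], "recall": state["recall"]},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
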