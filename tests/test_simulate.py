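"""Synthetic-data generator: genomes, gene packing, truth planting, pileups."""

import dataclasses

import numpy as np
import pytest

from poolvar.compare import POOLS
from poolvar.formats import read_pileup, var_type
from poolvar.simulate import (
    TruthDesign,
    _find_overlap_region,
    make_gene_models,
    make_genome,
    plant_variants,
    read_truth_tsv,
    simulate_pool_pileup,
    write_truth_tsv,
)

SMALL = dataclasses.replace(
    TruthDesign(),
    chrom_lengths=(("chrA", 16000), ("chrB", 14000)),
    n_genes=4,
    breed_shared=6,
    breed_high_only=4,
    breed_low_only=4,
    cross_common_high=5,
    cross_common_low=5,
    same_pos_diff_high_pairs=2,
    same_pos_diff_low_pairs=2,
)


class TestMakeGenome:
    def test_deterministic_for_fixed_seed(self):
        assert make_genome(SMALL, 7) == make_genome(SMALL, 7)

    def test_seeds_differ(self):
        g1, g2 = make_genome(SMALL, 7), make_genome(SMALL, 8)
        assert g1["chrA"] != g2["chrA"]

    def test_exact_lengths_and_alphabet(self):
        g = make_genome(SMALL, 1)
        assert len(g["chrA"]) == 16000 and len(g["chrB"]) == 14000
        assert set(g["chrA"]) <= set("ACGT")

    def test_minimum_length_enforced(self):
        d = dataclasses.replace(SMALL, chrom_lengths=(("c", 5000),))
        with pytest.raises(ValueError, match="10 kb"):
            make_genome(d, 1)


class TestMakeGeneModels:
    def test_overlap_pair_present(self):
        g = make_genome(SMALL, 1)
        models = make_gene_models(g, SMALL, 2)
        assert len(models) == SMALL.n_genes
        assert _find_overlap_region(models) is not None

    def test_zero_genes(self):
        d = dataclasses.replace(SMALL, n_genes=0, overlapping_gene_pairs=0)
        assert make_gene_models(make_genome(d, 1), d, 2) == []

    def test_all_models_satisfy_invariants(self):
        # GeneModel.__post_init__ enforces exon order/containment; also check
        # frame completeness, which the annotator requires
        g = make_genome(SMALL, 3)
        for m in make_gene_models(g, SMALL, 4):
            assert m.cds_length() % 3 == 0
            assert m.tss in (m.span.start, m.span.end)

    def test_infeasible_packing_raises(self):
        d = dataclasses.replace(SMALL, n_genes=40)
        with pytest.raises(ValueError, match="pack"):
            make_gene_models(make_genome(d, 1), d, 2)


class TestPlantVariants:
    def test_category_counts_match_design_exactly(self):
        g = make_genome(SMALL, 1)
        models = make_gene_models(g, SMALL, 2)
        truth = plant_variants(g, models, SMALL, 3)
        from collections import Counter

        counts = Counter(r.category for r in truth)
        assert counts["BY-shared"] == counts["WL-shared"] == SMALL.breed_shared
        assert counts["common-high"] == SMALL.cross_common_high
        assert counts["same-pos-diff-high"] == 2 * SMALL.same_pos_diff_high_pairs
        assert len(truth) == SMALL.n_truth_records

    def test_same_pos_diff_pairs_share_position_distinct_alts(self):
        g = make_genome(SMALL, 1)
        models = make_gene_models(g, SMALL, 2)
        truth = plant_variants(g, models, SMALL, 3)
        pairs = [r for r in truth if r.category == "same-pos-diff-high"]
        by_pos = {}
        for r in pairs:
            by_pos.setdefault((r.key.chrom, r.key.pos), []).append(r)
        for (chrom, pos), recs in by_pos.items():
            assert len(recs) == 2
            assert recs[0].key.alt != recs[1].key.alt
            assert {frozenset(r.pools) for r in recs} == {
                frozenset({"BY-H"}), frozenset({"WL-H"})
            }

    def test_all_zero_design_empty_truth(self):
        d = dataclasses.replace(
            SMALL, breed_shared=0, breed_high_only=0, breed_low_only=0,
            cross_common_high=0, cross_common_low=0,
            same_pos_diff_high_pairs=0, same_pos_diff_low_pairs=0,
        )
        g = make_genome(d, 1)
        models = make_gene_models(g, d, 2)
        assert plant_variants(g, models, d, 3) == []

    def test_keys_unique_and_ref_matches_genome(self):
        g = make_genome(SMALL, 9)
        models = make_gene_models(g, SMALL, 10)
        truth = plant_variants(g, models, SMALL, 11)
        keys = [r.key for r in truth]
        assert len(keys) == len(set(keys))
        for r in truth:
            seq = g[r.key.chrom]
            assert seq[r.key.pos - 1 : r.key.pos - 1 + len(r.key.ref)] == r.key.ref

    def test_truth_tsv_roundtrip(self, tmp_path):
        g = make_genome(SMALL, 1)
        models = make_gene_models(g, SMALL, 2)
        truth = plant_variants(g, models, SMALL, 3)
        p = tmp_path / "truth.tsv"
        write_truth_tsv(truth, p, seed=3)
        assert read_truth_tsv(p) == truth


class TestSimulatePileup:
    def _setup(self, **kw):
        d = dataclasses.replace(SMALL, **kw) if kw else SMALL
        g = make_genome(d, 1)
        models = make_gene_models(g, d, 2)
        truth = plant_variants(g, models, d, 3)
        return d, g, truth

    def test_noise_free_full_fraction_all_alt(self, tmp_path):
        d, g, truth = self._setup()
        # force every fraction to 1.0
        truth = [dataclasses.replace(r, fraction=1.0) for r in truth]
        p = simulate_pool_pileup(g, truth, "BY-H", d, 5, tmp_path / "p.txt")
        sites = {(s.chrom, s.pos): s for s in read_pileup(p, "BY-H")}
        for r in truth:
            if "BY-H" not in r.pools:
                continue
            s = sites[(r.key.chrom, r.key.pos)]
            ref_count = s.base_counts.get(r.key.ref[0], 0)
            if var_type(r.key) == "SNP":
                assert ref_count == 0, r.key  # every read carries the alt
            else:
                # every read carries the indel on its anchor match
                alt_allele = next(a for a in s.base_counts if a[0] in "+-")
                assert s.base_counts[alt_allele] == s.depth

    def test_zero_error_rate_means_no_mismatches_outside_truth(self, tmp_path):
        d, g, truth = self._setup()
        p = simulate_pool_pileup(g, truth, "WL-L", d, 6, tmp_path / "p.txt")
        anchors = {
            (r.key.chrom, pos)
            for r in truth
            for pos in range(r.key.pos, r.key.pos + len(r.key.ref))
        }
        for s in read_pileup(p, "WL-L"):
            if (s.chrom, s.pos) in anchors:
                continue
            assert set(s.base_counts) <= {s.ref_base}, (s.chrom, s.pos)

    def test_alt_fraction_matches_binomial_oracle_at_high_depth(self, tmp_path):
        """f=0.5, eps=0.01, deep coverage: observed alt fraction within
        3 s.e. of 0.5 * 0.99."""
        from poolvar.formats import VariantKey
        from poolvar.simulate import TruthRecord

        g = {"c": "ACGT" * 75}  # 300 bp is plenty for a single-site check
        rec = TruthRecord(
            VariantKey("c", 100, g["c"][99], "T" if g["c"][99] != "T" else "A"),
            "BY-high-specific", frozenset({"BY-H"}), 0.5,
        )
        deep = dataclasses.replace(SMALL, depth_mean=10_000.0, seq_error_rate=0.01)
        p = simulate_pool_pileup(g, [rec], "BY-H", deep, 7, tmp_path / "p.txt")
        site = next(
            s for s in read_pileup(p, "BY-H")
            if (s.chrom, s.pos) == (rec.key.chrom, rec.key.pos)
        )
        f_expect = 0.5 * 0.99
        n = site.depth
        se = (f_expect * (1 - f_expect) / n) ** 0.5
        observed = site.base_counts[rec.key.alt] / n
        assert abs(observed - f_expect) <= 3 * se

    def test_unknown_pool_rejected(self, tmp_path):
        d, g, truth = self._setup()
        with pytest.raises(ValueError, match="pool"):
            simulate_pool_pileup(g, truth, "XX", d, 5, tmp_path / "p.txt")
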