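"""Simulator ground truth, depth calibration and determinism."""

import numpy as np
import pytest

from covgeno import (
    RegionSpec,
    SimulationConfig,
    build_toy_locus,
    simulate_cohort,
    simulate_sample_reads,
)
from covgeno.feature_coverage import build_depth_table
from covgeno.locus_model import ALL_PROFILE, UNIQUE_PROFILE
from covgeno.synthetic_cohort import ConfigError


class TestBuildToyLocus:
    def test_defaults_have_six_deletion_members(self):
        features, copy_map = build_toy_locus(SimulationConfig())
        deleted = [f for f in features if f.role == "deletion_member"]
        assert len(deleted) == 6
        assert {f.feature_id for f in deleted} == {
            f"SVMP-{i}" for i in range(11, 17)
        }
        # the deletion haplotype carries zero copies of every deleted gene
        assert all(copy_map[f.feature_id] == (1, 0) for f in deleted)

    def test_empty_span_leaves_all_genes_diploid(self):
        features, copy_map = build_toy_locus(SimulationConfig(deletion_span=(1, 0)))
        array = [f for f in features if f.family == "SVMP"]
        assert all(f.role == "array_reference" for f in array)
        assert all(copy_map[f.feature_id] == (1, 1) for f in array)

    def test_two_gene_array_single_member_span(self):
        features, _ = build_toy_locus(
            SimulationConfig(n_array_genes=2, deletion_span=(2, 2))
        )
        roles = sorted(f.role for f in features if f.family == "SVMP")
        assert roles == ["array_reference", "deletion_member"]

    def test_span_outside_array_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_array_genes=5, deletion_span=(4, 7)).validate()

    def test_cn_target_on_separate_chromosome(self):
        features, _ = build_toy_locus(SimulationConfig())
        array_chroms = {f.chrom for f in features if f.family == "SVMP"}
        cn_chroms = {f.chrom for f in features if f.role in ("cn_target", "cn_reference")}
        assert array_chroms.isdisjoint(cn_chroms)


class TestSimulateSampleReads:
    def test_homodel_deletion_members_get_zero_reads_without_crossmap(self):
        cfg = SimulationConfig(cross_map=())
        features, _ = build_toy_locus(cfg)
        rng = np.random.default_rng(1)
        reads = simulate_sample_reads(
            features,
            {"sample_id": "s", "true_sv_genotype": "HomoDel", "true_copy_number": 4},
            cfg, rng,
        )
        deleted = {f.feature_id: f for f in features if f.role == "deletion_member"}
        for f in deleted.values():
            for s, e in f.exons:
                assert not any(
                    r.chrom == f.chrom and r.start < e and r.end > s for r in reads
                )

    def test_het_deletion_member_depth_is_half_lambda(self):
        """Monte-Carlo: Het deleted-exon mean depth ~ lambda/2 within 3 SE."""
        cfg = SimulationConfig(
            n_array_genes=2, deletion_span=(2, 2), exons_per_gene=1,
            cross_map=(), dup_rate=0.0, mean_depth=30.0,
        )
        features, _ = build_toy_locus(cfg)
        member = next(f for f in features if f.role == "deletion_member")
        rng = np.random.default_rng(5)
        n_rep = 1000
        depths = []
        truth = {"sample_id": "s", "true_sv_genotype": "Het", "true_copy_number": 2}
        for _ in range(n_rep):
            reads = simulate_sample_reads([member], truth, cfg, rng)
            span = sum(r.length for r in reads)
            depths.append(span / member.exon_length)
        mean = np.mean(depths)
        # depth = N * L / E with N ~ Poisson(lambda/2 * E/L)
        lam = cfg.mean_depth / 2
        se = lam / np.sqrt(n_rep * lam * cfg.exon_length / cfg.read_length)
        assert abs(mean - lam) < 3 * se

    def test_crossmapped_sink_exons_in_homodel(self, small_config, small_cohort):
        """A deleted gene's conserved exons show ~95% multimapped reads while
        their uniquely-mapped depth stays near zero."""
        reads, truth, features = small_cohort
        homodel = truth[truth["true_sv_genotype"] == "HomoDel"]["sample_id"]
        (cm,) = small_config.cross_map
        depth = build_depth_table(
            {s: reads[s] for s in homodel}, features, (UNIQUE_PROFILE, ALL_PROFILE)
        )
        sink = depth[
            (depth["feature_id"] == cm.sink_gene)
            & (depth["exon_index"].isin([str(i) for i in cm.exon_indices]))
        ]
        mm = sink[sink["profile_name"] == "all"]["multimap_fraction"]
        assert abs(mm.mean() - cm.ambiguous_fraction) < 0.03
        unique_depth = sink[sink["profile_name"] == "unique"]["mean_depth"]
        assert unique_depth.mean() < 0.1 * small_config.mean_depth


class TestSimulateCohort:
    def test_same_config_and_seed_identical(self, small_config):
        reads_a, truth_a = simulate_cohort(small_config)
        reads_b, truth_b = simulate_cohort(small_config)
        assert truth_a.equals(truth_b)
        assert reads_a == reads_b

    def test_degenerate_frequencies_all_homoref(self):
        cfg = SimulationConfig(
            regions={"r": RegionSpec(20, (1.0, 0.0, 0.0))}, cross_map=(), seed=3
        )
        _, truth = simulate_cohort(cfg)
        assert (truth["true_sv_genotype"] == "HomoRef").all()

    def test_no_regions_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(regions={}).validate()

    def test_rangewide_cohort_genotype_counts(self):
        """139 samples at the range-wide class frequencies give expected
        counts ~(123, 5, 11), within multinomial tolerance (4 sigma)."""
        freqs = (123 / 139, 5 / 139, 11 / 139)
        cfg = SimulationConfig(
            regions={"range": RegionSpec(139, freqs)}, cross_map=(), seed=23
        )
        _, truth = simulate_cohort(cfg)
        counts = truth["true_sv_genotype"].value_counts()
        for cls, expected, p in zip(
            ("HomoRef", "Het", "HomoDel"), (123, 5, 11), freqs
        ):
            sigma = np.sqrt(139 * p * (1 - p))
            assert abs(counts.get(cls, 0) - expected) < 4 * sigma + 1

    def test_depth_conservation_on_diploid_bases(self):
        """Mean duplicate-free depth over copy-2 exon bases converges to the
        configured mean depth (rel. error < 2% over >= 1e5 bases)."""
        cfg = SimulationConfig(
            regions={"r": RegionSpec(16, (1.0, 0.0, 0.0))}, cross_map=(), seed=9
        )
        features, _ = build_toy_locus(cfg)
        diploid = [f for f in features if f.role == "array_reference"]
        n_bases = 16 * sum(f.exon_length for f in diploid)
        assert n_bases >= 1e5
        reads, _ = simulate_cohort(cfg)
        depth = build_depth_table(reads, features, (ALL_PROFILE,), per_exon=False)
        rows = depth[depth["feature_id"].isin([f.feature_id for f in diploid])]
        observed = rows["mean_depth"].mean()
        assert abs(observed - cfg.mean_depth) / cfg.mean_depth < 0.02

    def test_truth_marginals_match_requested_frequencies(self, small_cohort):
        _, truth, _ = small_cohort
        n = len(truth)
        for cls in ("HomoRef", "Het", "HomoDel"):
            k = (truth["true_sv_genotype"] == cls).sum()
            p = 1 / 3
            assert abs(k - n * p) <= 4 * np.sqrt(n * p * (1 - p))

    def test_duplicate_fraction_near_configured_rate(self, small_cohort):
        reads, _, _ = small_cohort
        flat = [r for rs in reads.values() for r in rs]
        frac = np.mean([r.is_duplicate for r in flat])
        assert abs(frac - 0.05) < 0.01
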