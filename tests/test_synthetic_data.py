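import math

import numpy as np
import pytest

from introcold.regulon_scan import scan_dre
from introcold.synthetic_data import (
    ConfigurationError,
    PROMOTER_LENGTH,
    SimulationConfig,
    generate_dataset,
    generate_genome_annotation,
    generate_promoters,
)

from conftest import SMALL_PLANTED


class TestConfig:
    def test_counts_exceeding_genes_rejected(self):
        with pytest.raises(ConfigurationError, match="planted counts"):
            SimulationConfig(n_genes=10, planted_counts={"common_induced": 11})

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ConfigurationError, match="strictly increasing"):
            SimulationConfig(timepoints=(2, 2, 6))

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown truth classes"):
            SimulationConfig(planted_counts={"wobbly": 5})


class TestGenerateDataset:
    def test_seeded_determinism_bitwise(self, small_config):
        m1, s1, t1 = generate_dataset(small_config)
        m2, s2, t2 = generate_dataset(small_config)
        assert (m1.values.to_numpy() == m2.values.to_numpy()).all()
        assert s1 == s2
        assert (t1.classes == t2.classes).all()

    def test_dimensions_match_design(self, small_config, small_dataset):
        matrix, samples, _ = small_dataset
        expected_cols = 2 * (1 + len(small_config.timepoints)) * small_config.n_replicates
        assert matrix.values.shape == (small_config.n_genes, expected_cols)
        assert (matrix.values.to_numpy() > 0).all()

    def test_all_null_config_has_no_differential_truth(self):
        cfg = SimulationConfig(seed=1, n_genes=50, planted_counts={})
        _, _, truth = generate_dataset(cfg)
        assert set(truth.classes) == {"null"}

    def test_planted_inequalities_on_noiseless_means(self):
        cfg = SimulationConfig(seed=2, n_genes=120, noise_sd_log2=0.0,
                               planted_counts=dict(SMALL_PLANTED))
        matrix, _, truth = generate_dataset(cfg)

        def mean_ratio(gene, genotype, t):
            cold = matrix.values.loc[gene, matrix.select(genotype, "cold", t)].mean()
            ctrl = matrix.values.loc[gene, matrix.select(genotype, "control")].mean()
            return cold / ctrl

        for gene in truth.genes_of("common_induced"):
            for genotype in ("recurrent", "introgression"):
                assert max(mean_ratio(gene, genotype, t) for t in cfg.timepoints) > 5

        for gene in truth.genes_of("constitutive_up_il"):
            il_ctrl = matrix.values.loc[gene, matrix.select("introgression", "control")].mean()
            rec_ctrl = matrix.values.loc[gene, matrix.select("recurrent", "control")].mean()
            assert il_ctrl / rec_ctrl > 5
            for t in cfg.timepoints:
                il_t = matrix.values.loc[gene, matrix.select("introgression", "cold", t)].mean()
                rec_t = matrix.values.loc[gene, matrix.select("recurrent", "cold", t)].mean()
                assert il_t / rec_t > 5
                for genotype in ("recurrent", "introgression"):
                    assert mean_ratio(gene, genotype, t) < 2

        for gene in truth.genes_of("il_specific_induced"):
            assert max(mean_ratio(gene, "introgression", t) for t in cfg.timepoints) > 5
            for t in cfg.timepoints:
                assert mean_ratio(gene, "recurrent", t) < 2


class TestPromoters:
    def test_lengths_and_planted_words(self, small_config, small_dataset):
        _, _, truth = small_dataset
        promoters = generate_promoters(truth, small_config)
        assert all(len(s) == PROMOTER_LENGTH for s in promoters.values())
        for gene, plants in truth.motif_offsets.items():
            for plant in plants:
                word = promoters[gene][plant.offset:plant.offset + 6]
                assert word == plant.word
                hits = scan_dre((gene, promoters[gene]))
                assert any(h.offset == plant.offset for h in hits)

    def test_motif_free_background_rejection_toy(self):
        cfg = SimulationConfig(seed=3, n_genes=10, motif_plant_rate=0.0, planted_counts={})
        _, _, truth = generate_dataset(cfg)
        promoters = generate_promoters(truth, cfg, reject_background_hits=True)
        assert all(scan_dre((g, s)) == [] for g, s in promoters.items())

    def test_accidental_hits_near_binomial_expectation(self):
        cfg = SimulationConfig(seed=4, n_genes=500, motif_plant_rate=0.0, planted_counts={})
        _, _, truth = generate_dataset(cfg)
        promoters = generate_promoters(truth, cfg)
        total = sum(len(scan_dre((g, s))) for g, s in promoters.items())
        n_positions = 500 * (PROMOTER_LENGTH - 5)
        p = 4 / 4096  # 2 words + 2 reverse complements, each 4^-6
        expected = n_positions * p
        sd = math.sqrt(n_positions * p * (1 - p))
        assert abs(total - expected) <= 3 * sd

    def test_plant_rate_scales_with_designated_set(self, small_config, small_dataset):
        _, _, truth = small_dataset
        generate_promoters(truth, small_config)
        planted = set(truth.motif_offsets)
        designated = set(truth.genes_of("common_induced"))
        assert planted <= designated
        # rate 0.5 over 20 genes: expect roughly half planted
        assert 3 <= len(planted) <= 17


class TestAnnotation:
    def test_segment_count_and_disjointness(self, small_config, small_dataset):
        _, _, truth = small_dataset
        ann = generate_genome_annotation(truth, small_config)
        assert len(ann.segments) == 17
        by_chrom = {}
        for s in ann.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_gene_placement_consistent_with_truth(self, small_config, small_dataset):
        _, _, truth = small_dataset
        ann = generate_genome_annotation(truth, small_config)
        by_name = {g.name: g for g in ann.genes}
        segs = {s.name: s for s in ann.segments}
        for gene, seg_name in truth.placement.items():
            g = by_name[gene]
            assert 0 <= g.start < g.end <= small_config.chromosome_length
            if seg_name:
                s = segs[seg_name]
                assert g.chrom == s.chrom and g.start >= s.start and g.end <= s.end
            else:
                assert all(
                    not (g.chrom == s.chrom and max(g.start, s.start) < min(g.end, s.end))
                    for s in ann.segments
                )

    def test_each_gene_has_at_most_five_terms(self, small_config, small_dataset):
        _, _, truth = small_dataset
        ann = generate_genome_annotation(truth, small_config)
        per_gene = {}
        for term, gs in ann.go_map.items():
            for g in gs.genes:
                per_gene[g] = per_gene.get(g, 0) + 1
        assert max(per_gene.values()) <= 5

    def test_enriched_term_concentrated_in_designated_class(self, small_config, small_dataset):
        _, _, truth = small_dataset
        ann = generate_genome_annotation(truth, small_config)
        term_genes = set(ann.go_map[small_config.go_enriched_term].genes)
        target = set(truth.genes_of(small_config.go_enriched_class))
        others = set(truth.classes.index) - target
        rate_in = len(term_genes & target) / len(target)
        rate_out = len(term_genes & others) / len(others)
        assert rate_in > 3 * rate_out

    def test_annotation_deterministic(self, small_config, small_dataset):
        _, _, truth = small_dataset
        a1 = generate_genome_annotation(truth, small_config)
        a2 = generate_genome_annotation(truth, small_config)
        assert a1.segments == a2.segments and a1.genes == a2.genes and a1.qtls == a2.qtls
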