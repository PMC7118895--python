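"""Properties of the synthetic trio generator: determinism, conservation,
parameter recovery."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from triobin import parentage, simulate
from triobin.simulate import (
    MATERNAL,
    PATERNAL,
    PanelMember,
    SimConfig,
    simulate_f1_long_reads,
    simulate_hic_pairs,
    simulate_parent_genomes,
    simulate_parent_short_reads,
    simulate_pileups,
    simulate_trio_genotypes,
)


class TestParentGenomes:
    def test_zero_divergence_identical(self):
        cfg = SimConfig(genome_length=20_000, n_chromosomes=1, divergence=0.0, seed=1)
        mat, pat, truth = simulate_parent_genomes(cfg)
        assert mat == pat
        assert len(truth.variants) == 0

    def test_realized_divergence_within_tolerance(self):
        cfg = SimConfig(genome_length=500_000, n_chromosomes=2, divergence=0.012, seed=1)
        _, _, truth = simulate_parent_genomes(cfg)
        realized = (truth.variants["kind"] == "SNP").sum() / 1_000_000
        assert abs(realized - 0.012) / 0.012 <= 0.1

    def test_deterministic(self, tiny_config):
        a = simulate_parent_genomes(tiny_config)
        b = simulate_parent_genomes(tiny_config)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].variants.equals(b[2].variants)

    def test_excessive_divergence_rejected(self):
        with pytest.raises(ValueError, match="divergence"):
            SimConfig(divergence=0.6)

    def test_variants_match_sequences(self, tiny_genomes):
        """Every truth SNP shows the recorded alleles in the two genomes."""
        mat, pat, truth = tiny_genomes
        snps = truth.variants.query("kind == 'SNP'")
        for row in snps.sample(min(len(snps), 50), random_state=0).itertuples():
            assert mat[row.chrom][row.pos] == row.mat_allele
            assert pat[row.chrom][row.pat_pos] == row.pat_allele


class TestLongReads:
    def test_error_free_reads_are_substrings(self):
        cfg = SimConfig(
            genome_length=30_000, n_chromosomes=1, long_read_error=0.0,
            long_read_depth=0.5, long_read_mean=2_000, seed=2,
        )
        mat, pat, _ = simulate_parent_genomes(cfg)
        reads, truth = simulate_f1_long_reads(mat, pat, cfg)
        genomes = {MATERNAL: mat, PATERNAL: pat}
        for read, row in zip(reads, truth.reads.itertuples()):
            assert read.seq == genomes[row.haplotype][row.chrom][row.start : row.end]

    def test_total_length_matches_depth(self, trio_sim):
        total = sum(len(r.seq) for r in trio_sim["reads"])
        target = 20 * 2_000_000  # depth x diploid genome size
        assert abs(total - target) / target <= 0.1

    def test_haplotype_balance(self, trio_sim):
        counts = trio_sim["truth_reads"].reads["haplotype"].value_counts()
        n = counts.sum()
        # 5-sigma binomial band around 50%
        band = 5 * 0.5 / np.sqrt(n)
        assert abs(counts[MATERNAL] / n - 0.5) <= band

    def test_truth_covers_every_read(self, trio_sim):
        assert len(trio_sim["truth_reads"].reads) == len(trio_sim["reads"])
        assert trio_sim["truth_reads"].reads["read_id"].is_unique

    def test_nonpositive_depth_rejected(self, tiny_genomes, tiny_config):
        mat, pat, _ = tiny_genomes
        cfg = replace(tiny_config, long_read_depth=0.0)
        with pytest.raises(ValueError, match="depth"):
            simulate_f1_long_reads(mat, pat, cfg)


class TestShortReads:
    def test_error_free_reads_match_genome(self):
        cfg = SimConfig(
            genome_length=20_000, n_chromosomes=1, short_read_error=0.0,
            within_species_het=0.0, short_read_depth=2.0, seed=3,
        )
        mat, _, _ = simulate_parent_genomes(cfg)
        reads = simulate_parent_short_reads(mat, cfg, MATERNAL)
        from triobin._seq import revcomp

        genome = mat["chr1"]
        for r in reads[:200]:
            assert r.seq in genome or revcomp(r.seq) in genome

    def test_base_count_matches_depth(self, tiny_genomes, tiny_config):
        mat, _, _ = tiny_genomes
        reads = simulate_parent_short_reads(mat, tiny_config, MATERNAL)
        total = sum(len(r.seq) for r in reads)
        target = tiny_config.short_read_depth * sum(len(s) for s in mat.values())
        assert abs(total - target) / target <= 0.1

    def test_deterministic(self, tiny_genomes, tiny_config):
        mat, _, _ = tiny_genomes
        a = simulate_parent_short_reads(mat, tiny_config, MATERNAL)
        b = simulate_parent_short_reads(mat, tiny_config, MATERNAL)
        assert a == b

    def test_read_longer_than_chromosome_rejected(self, tiny_config):
        cfg = replace(tiny_config, short_read_length=200)
        with pytest.raises(ValueError, match="read length"):
            simulate_parent_short_reads({"chr1": "ACGT" * 10}, cfg, MATERNAL)


class TestHiCPairs:
    def test_no_junctions_when_rate_zero(self, tiny_genomes, tiny_config):
        mat, pat, truth = tiny_genomes
        cfg = replace(tiny_config, junction_rate=0.0)
        _, _, _, th = simulate_hic_pairs(mat, pat, cfg, truth)
        assert not th.hic_pairs["chimera1"].any()
        assert not th.hic_pairs["chimera2"].any()

    def test_own_haplotype_scores_at_least_other(self, tiny_genomes, tiny_config):
        mat, pat, truth = tiny_genomes
        cfg = replace(tiny_config, hic_read_error=0.0)
        _, _, _, th = simulate_hic_pairs(mat, pat, cfg, truth)
        tp = th.hic_pairs
        mat_pairs = tp[tp.haplotype == MATERNAL]
        pat_pairs = tp[tp.haplotype == PATERNAL]
        assert (mat_pairs.score_maternal >= mat_pairs.score_paternal).all()
        assert (pat_pairs.score_paternal >= pat_pairs.score_maternal).all()

    def test_truth_count_conserved(self, tiny_genomes, tiny_config):
        mat, pat, truth = tiny_genomes
        m1, m2, sams, th = simulate_hic_pairs(mat, pat, tiny_config, truth)
        assert len(m1) == len(m2) == len(th.hic_pairs) == tiny_config.hic_n_pairs
        # one primary record per mate per assembly
        assert len(sams["maternal"]) == 2 * tiny_config.hic_n_pairs

    def test_nonpositive_pairs_rejected(self, tiny_genomes, tiny_config):
        mat, pat, truth = tiny_genomes
        with pytest.raises(ValueError, match="hic_n_pairs"):
            simulate_hic_pairs(mat, pat, replace(tiny_config, hic_n_pairs=0), truth)


class TestTrioGenotypes:
    def test_zero_error_child_is_consistent(self, tmp_path):
        cfg = SimConfig(seed=4, genotype_error=0.0)
        vcf_text, _ = simulate_trio_genotypes(2_000, None, cfg)
        path = tmp_path / "trio.vcf"
        path.write_text(vcf_text)
        report = parentage.count_exclusions(path, "sire", "dam", "child")
        assert report.n_exclusions == 0

    def test_site_count(self):
        cfg = SimConfig(seed=4)
        vcf_text, truth = simulate_trio_genotypes(500, None, cfg)
        data_lines = [l for l in vcf_text.splitlines() if not l.startswith("#")]
        assert len(data_lines) == 500
        assert truth.genotypes["site"].nunique() == 500

    def test_fixed_lineage_alleles_give_signature(self, tmp_path):
        cfg = SimConfig(seed=5, genotype_error=0.0)
        n = 300
        freqs = (np.zeros(n), np.ones(n))  # sire lineage ref, dam lineage alt
        vcf_text, _ = simulate_trio_genotypes(n, freqs, cfg)
        path = tmp_path / "fixed.vcf"
        path.write_text(vcf_text)
        report = parentage.count_exclusions(path, "sire", "dam", "child")
        assert report.n_signature_ignored == n
        assert report.n_sites_analyzed == 0

    def test_invalid_freqs_rejected(self):
        cfg = SimConfig(seed=4)
        with pytest.raises(ValueError, match="biallelic"):
            simulate_trio_genotypes(10, (np.full(10, 1.5), np.zeros(10)), cfg)


class TestPileups:
    def test_zero_divergence_all_reference(self):
        cfg = SimConfig(seed=6, within_species_het=0.0)
        ref = {"chr1": "ACGT" * 500}
        pileups, truth = simulate_pileups(
            ref, [PanelMember("s1", 0.0)], cfg, seq_error=0.0
        )
        assert len(truth.pileup_sites) == 0
        for line in pileups["s1"].splitlines():
            bases = line.split("\t")[4]
            assert set(bases) <= {"."}

    def test_hom_alt_fraction_tracks_divergence(self):
        cfg = SimConfig(seed=6, within_species_het=0.0)
        ref = {"chr1": "ACGT" * 25_000}
        d = 0.006
        _, truth = simulate_pileups(ref, [PanelMember("s1", d)], cfg)
        n_hom = (truth.pileup_sites["genotype"] == "HOM_ALT").sum()
        realized = n_hom / 100_000
        assert abs(realized - d) / d <= 0.2

    def test_depth_column_consistent(self):
        cfg = SimConfig(seed=6)
        ref = {"chr1": "ACGT" * 100}
        pileups, _ = simulate_pileups(ref, [PanelMember("s1", 0.01)], cfg)
        for line in pileups["s1"].splitlines():
            fields = line.split("\t")
            assert int(fields[3]) == len(fields[4]) == len(fields[5])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            simulate_pileups({"chr1": "ACGT"}, [], SimConfig(seed=6))


class TestGapAndTelomereFixtures:
    def test_planted_statuses_recorded(self, tiny_config):
        fx = simulate.make_gap_fixture(tiny_config)
        truth = fx.truth.gaps
        assert set(truth["target"]) == {"A", "B"}
        assert (truth.query("target == 'A'")["status"].tolist()) == [
            "CLOSED", "CLOSED", "TRANS_SCAFFOLD", "OPEN", "OPEN", "UNPLACED",
        ]

    def test_flank_exceeding_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            simulate.GapFixtureConfig(flank=700, spacer=600)

    def test_telomere_fixture_counts(self, tiny_config):
        seqs = simulate.make_telomere_fixture(tiny_config, repeat_counts=(6, 0))
        assert seqs["seq1_n6"].endswith("TTAGGG" * 6)
        assert "TTAGGG" not in seqs["seq2_n0"][-1000:]
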