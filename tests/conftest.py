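"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

from dataclasses import replace

import pytest

from triobin import binning, kmers, simulate


@pytest.fixture(scope="session")
def study_config() -> simulate.SimConfig:
    """The default study conditions: two 500-kb chromosomes per parent at
    1.2% SNP divergence plus ~0.1% short indels, error-free 30x parental
    short reads, 15-kb-mean F1 long reads at 20x with 10% error."""
    return simulate.SimConfig(
        genome_length=500_000,
        n_chromosomes=2,
        divergence=0.012,
        indel_rate=0.077,
        short_read_error=0.0,
        long_read_mean=15_000,
        long_read_depth=20.0,
        long_read_error=0.10,
        seed=1,
    )


@pytest.fixture(scope="session")
def trio_sim(study_config):
    """Genomes, marker sets, long reads and binning calls at study scale.

    Built once per session; shared by the binning unit tests and the
    acceptance checks.
    """
    cfg = study_config
    mat, pat, truth_g = simulate.simulate_parent_genomes(cfg)
    sr_m = simulate.simulate_parent_short_reads(mat, cfg, simulate.MATERNAL)
    sr_p = simulate.simulate_parent_short_reads(pat, cfg, simulate.PATERNAL)
    mconf = kmers.MarkerConfig(k=21)
    mat_counts = kmers.count_kmers((r.seq for r in sr_m), 21, "maternal")
    pat_counts = kmers.count_kmers((r.seq for r in sr_p), 21, "paternal")
    mat_markers, pat_markers = kmers.build_marker_sets(mat_counts, pat_counts, mconf)
    reads, truth_r = simulate.simulate_f1_long_reads(mat, pat, cfg)
    bins, calls, report = binning.bin_reads(
        reads, mat_markers, pat_markers, genome_size=cfg.genome_length * cfg.n_chromosomes
    )
    return {
        "config": cfg,
        "maternal": mat,
        "paternal": pat,
        "truth_genomes": truth_g,
        "maternal_markers": mat_markers,
        "paternal_markers": pat_markers,
        "reads": reads,
        "truth_reads": truth_r,
        "bins": bins,
        "calls": calls,
        "report": report,
    }


@pytest.fixture()
def tiny_config() -> simulate.SimConfig:
    """A fast configuration for unit tests (two 50-kb chromosomes)."""
    return simulate.SimConfig(
        genome_length=50_000, n_chromosomes=2, seed=11, hic_n_pairs=300
    )


@pytest.fixture()
def tiny_genomes(tiny_config):
    return simulate.simulate_parent_genomes(tiny_config)


def error_free(config: simulate.SimConfig) -> simulate.SimConfig:
    return replace(
        config, long_read_error=0.0, short_read_error=0.0, hic_read_error=0.0
    )
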