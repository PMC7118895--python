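"""End-to-end pipeline over the synthetic trio: simulate through QC stages."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import binning, gaps, hic, io, kmers, parentage, phasing, simulate
from .config import PipelineConfig


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    simulate -> markers -> bin-reads -> bin-hic -> parentage -> phase-qc ->
    gaps/telomeres.  Every output under ``config.out_dir`` is reproducible
    from (config, seed); each report starts with a provenance header.
    Returns a dict of stage summaries.  A stage failure propagates after the
    last completed stage is noted in ``checkpoint.txt``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    enabled = set(config.stages)
    summary: dict = {"provenance": config.provenance()}
    checkpoint = out / "checkpoint.txt"

    def _done(stage: str) -> None:
        checkpoint.write_text(f"last completed stage: {stage}\n")

    def _report(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(config.provenance() + "\n")
            frame.to_csv(fh, sep="\t", index=False)

    try:
        # --- simulate ------------------------------------------------------
        mat, pat, truth_g = simulate.simulate_parent_genomes(sim)
        long_reads, truth_reads = simulate.simulate_f1_long_reads(mat, pat, sim)
        if "simulate" in enabled:
            io.write_fasta(out / "maternal.fasta", mat)
            io.write_fasta(out / "paternal.fasta", pat)
            io.write_fastq(out / "f1_long_reads.fastq", long_reads)
            truth_g.to_tsv(out / "truth")
            truth_reads.to_tsv(out / "truth")
            summary["simulate"] = {
                "n_variants": len(truth_g.variants),
                "n_long_reads": len(long_reads),
            }
            _done("simulate")

        # --- markers -------------------------------------------------------
        if enabled & {"markers", "bin-reads"}:
            mat_sr = simulate.simulate_parent_short_reads(mat, sim, simulate.MATERNAL)
            pat_sr = simulate.simulate_parent_short_reads(pat, sim, simulate.PATERNAL)
            k = config.markers.k
            mat_counts = kmers.count_kmers((r.seq for r in mat_sr), k, "maternal")
            pat_counts = kmers.count_kmers((r.seq for r in pat_sr), k, "paternal")
            mat_markers, pat_markers = kmers.build_marker_sets(
                mat_counts, pat_counts, config.markers
            )
            if "markers" in enabled:
                mat_markers.to_tsv(out / "maternal_markers.tsv")
                pat_markers.to_tsv(out / "paternal_markers.tsv")
                summary["markers"] = kmers.marker_summary(mat_markers, pat_markers)
                _done("markers")

        # --- bin-reads -----------------------------------------------------
        if "bin-reads" in enabled:
            bins, calls, report = binning.bin_reads(
                long_reads,
                mat_markers,
                pat_markers,
                normalize=config.normalize_binning,
                genome_size=sim.genome_length * sim.n_chromosomes,
            )
            for name, bucket in (
                ("maternal", bins[binning.MATERNAL]),
                ("paternal", bins[binning.PATERNAL]),
                ("unclassified", bins[binning.UNCLASSIFIED]),
            ):
                io.write_fastq(out / f"{name}.fq", bucket)
            _report("binning_report.tsv", report.to_frame())
            accuracy = binning.evaluate_binning(calls, truth_reads.reads)
            summary["bin-reads"] = {
                "fraction_classified": report.fraction_of_total_length_classified,
                "fraction_with_marker": report.fraction_of_total_length_with_marker,
                "misassignment_rate": accuracy["misassignment_rate"],
            }
            _done("bin-reads")

        # --- bin-hic -------------------------------------------------------
        if "bin-hic" in enabled:
            m1, m2, sams, truth_hic = simulate.simulate_hic_pairs(
                mat, pat, sim, truth_g
            )
            sets, pair_calls, counts = hic.partition_hic(
                sams["maternal"], sams["paternal"], margin=config.hic_margin
            )
            for call_name, ids in sets.items():
                (out / f"hic_{call_name.lower()}.ids").write_text(
                    "\n".join(sorted(ids)) + ("\n" if ids else "")
                )
            _report(
                "hic_report.tsv",
                pd.DataFrame([counts]),
            )
            summary["bin-hic"] = counts
            _done("bin-hic")

        # --- parentage -----------------------------------------------------
        if "parentage" in enabled:
            vcf_text, _ = simulate.simulate_trio_genotypes(
                config.n_trio_sites, None, sim
            )
            vcf_path = out / "trio.vcf"
            io.write_vcf(vcf_path, vcf_text)
            verdict = parentage.parentage_report(
                vcf_path,
                "child",
                ["sire", "uSire1", "uSire2", "uSire3", "uSire4"],
                ["dam", "uDam1"],
                true_sire="sire",
                true_dam="dam",
            )
            _report(
                "parentage_report.tsv",
                pd.DataFrame(
                    [
                        (
                            r.sire_id,
                            r.dam_id,
                            r.n_sites_analyzed,
                            r.n_signature_ignored,
                            r.n_exclusions,
                            r.exclusion_rate,
                        )
                        for r in verdict["reports"]
                    ],
                    columns=[
                        "sire",
                        "dam",
                        "n_analyzed",
                        "n_signature",
                        "n_exclusions",
                        "exclusion_rate",
                    ],
                ),
            )
            summary["parentage"] = {
                "assigned_sire": verdict["sire"]["assigned"],
                "assigned_dam": verdict["dam"]["assigned"],
            }
            _done("parentage")

        # --- phase-qc ------------------------------------------------------
        if "phase-qc" in enabled:
            panel = [
                simulate.PanelMember(f"cattle{i + 1}", 0.006) for i in range(3)
            ] + [simulate.PanelMember(f"yak{i + 1}", 0.001) for i in range(3)]
            pileups, _ = simulate.simulate_pileups(mat, panel, sim)
            rates = {
                sid: phasing.pileup_to_window_rates(
                    list(io.parse_pileup(text.splitlines()))
                )
                for sid, text in pileups.items()
            }
            comparison = phasing.compare_panels(
                rates,
                {m.sample_id for m in panel if m.sample_id.startswith("yak")},
                {m.sample_id for m in panel if m.sample_id.startswith("cattle")},
            )
            _report(
                "phase_qc.tsv",
                pd.DataFrame(
                    {
                        "chrom": [c for c, _ in comparison.chrom_starts],
                        "start": [s for _, s in comparison.chrom_starts],
                        "mean_own_species": comparison.mean_a,
                        "mean_other_species": comparison.mean_b,
                    }
                ),
            )
            summary["phase-qc"] = {
                "fraction_other_species_higher": 1.0 - comparison.fraction_a_higher
                if comparison.fraction_a_higher == comparison.fraction_a_higher
                else float("nan"),
            }
            _done("phase-qc")

        # --- gaps / telomeres ---------------------------------------------
        if "gaps" in enabled:
            fixture = simulate.make_gap_fixture(sim)
            target_gaps = {
                label: gaps.find_assembly_gaps(asm)
                for label, asm in fixture.targets.items()
            }
            calls = {
                label: gaps.classify_gap_closure(
                    fixture.flank_sams[label], target_gaps[label]
                )
                for label in fixture.targets
            }
            table = gaps.compare_closures(calls["A"], calls["B"])
            with open(out / "gap_consistency.tsv", "w") as fh:
                fh.write(config.provenance() + "\n")
                table.to_csv(fh, sep="\t")
            summary["gaps"] = {
                label: {c.gap_id: c.status for c in cs} for label, cs in calls.items()
            }
            _done("gaps")

        if "telomeres" in enabled:
            seqs = simulate.make_telomere_fixture(sim)
            calls = gaps.find_telomeres(seqs)
            _report(
                "telomeres.tsv",
                pd.DataFrame(
                    [(c.seq_id, c.count, c.is_telomeric) for c in calls],
                    columns=["seq_id", "motif_count", "is_telomeric"],
                ),
            )
            summary["telomeres"] = {c.seq_id: c.count for c in calls}
            _done("telomeres")
    except Exception:
        io.log("pipeline", f"stage failed; see {checkpoint}")
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
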