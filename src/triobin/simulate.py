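"""Synthetic interspecies-trio data generator.

Emulates the inputs of a trio-binning assembly study: two parental genomes
diverged at a configurable SNP/indel rate (default 1.2% SNPs, the
heterozygosity regime of a yak x cattle F1 hybrid), F1 long reads with
per-read haplotype-of-origin truth, parental short reads, junction-chimeric
Hi-C pairs scored against both haplotype assemblies, trio + unrelated
genotypes with controllable genotyping error, per-individual pileups over a
reference, and toy assemblies containing N-gaps and telomeric repeats.

Every generator is deterministic given (config, seed): randomness flows from
``numpy.random.default_rng([seed, stage_tag])`` so stages are independent
but reproducible.  Truth coordinates are 0-based half-open on the emitting
haplotype; 1-based appears only in serialized VCF/pileup/SAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from . import _seq, io

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"

JUNCTION = "GATCGATC"

# stage tags -> stable integers mixed into the per-stage RNG seed
_STAGE = {
    "genomes": 1,
    "long_reads": 2,
    "short_reads_mat": 3,
    "short_reads_pat": 4,
    "hic": 5,
    "genotypes": 6,
    "pileups": 7,
    "gaps": 8,
    "telomeres": 9,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic trio.

    Defaults mirror the study regime: 1.2% SNP divergence between the
    parental lineages with a small admixture of 1-10 bp indels, 15-kb-mean
    long reads at 20x diploid coverage with 10% per-base error, 2x150 bp
    parental short reads at 30x, and ~2% genotyping error for the
    low-coverage parentage panel.
    """

    genome_length: int = 500_000  # bp per chromosome
    n_chromosomes: int = 2
    divergence: float = 0.012  # expected SNP rate between lineages
    indel_rate: float = 0.077  # fraction of divergent events that are indels
    within_species_het: float = 0.001  # parental diploid heterozygosity
    long_read_mean: int = 15_000
    long_read_error: float = 0.10
    error_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm:ins:del
    long_read_depth: float = 20.0  # fold coverage of the diploid genome
    short_read_length: int = 150
    short_read_depth: float = 30.0
    short_read_error: float = 0.001
    hic_n_pairs: int = 10_000
    junction_rate: float = 0.2  # fraction of Hi-C reads that are chimeras
    hic_read_error: float = 0.002
    genotype_error: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "divergence": self.divergence,
            "indel_rate": self.indel_rate,
            "within_species_het": self.within_species_het,
            "long_read_error": self.long_read_error,
            "short_read_error": self.short_read_error,
            "junction_rate": self.junction_rate,
            "hic_read_error": self.hic_read_error,
            "genotype_error": self.genotype_error,
        }
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} must be in [0, 1]")
        if self.divergence >= 0.5:
            raise ValueError(
                "divergence >= 0.5 breaks the marker-construction assumptions"
            )
        positive = {
            "genome_length": self.genome_length,
            "n_chromosomes": self.n_chromosomes,
            "long_read_mean": self.long_read_mean,
            "short_read_length": self.short_read_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name}={value} must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])


@dataclass
class TruthTable:
    """Ground-truth labels for everything a generator emits.

    Each table is a DataFrame; coordinates 0-based half-open on the emitting
    haplotype.  Only the tables relevant to the producing operation are
    populated.
    """

    variants: pd.DataFrame | None = None  # chrom,pos,end,pat_pos,kind,mat_allele,pat_allele
    reads: pd.DataFrame | None = None  # read_id,haplotype,chrom,start,end,n_errors
    hic_pairs: pd.DataFrame | None = None
    genotypes: pd.DataFrame | None = None
    pileup_sites: pd.DataFrame | None = None
    gaps: pd.DataFrame | None = None

    def to_tsv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "variants",
            "reads",
            "hic_pairs",
            "genotypes",
            "pileup_sites",
            "gaps",
        ):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    ascii_codes = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    return ascii_codes.tobytes().decode("ascii")


def _matrix_to_strings(matrix: np.ndarray) -> list[str]:
    ascii_codes = np.frombuffer(b"ACGT", dtype=np.uint8)[matrix]
    width = matrix.shape[1]
    return [b.decode("ascii") for b in ascii_codes.view(f"S{width}").ravel()]


# ---------------------------------------------------------------------------
# parental genomes


def simulate_parent_genomes(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], TruthTable]:
    """Two parental genomes diverged by SNPs and short indels.

    The maternal genome is drawn uniformly at random; the paternal genome is
    derived from it by placing divergence events (SNP with probability
    1-indel_rate, else a 1-10 bp insertion or deletion) at a per-base event
    rate of ``divergence / (1 - indel_rate)``, so the realized SNP rate has
    expectation ``divergence``.  The truth table lists every variant with
    both maternal and paternal coordinates.
    """
    rng = config.rng("genomes")
    maternal: dict[str, str] = {}
    paternal: dict[str, str] = {}
    rows: list[tuple] = []
    event_rate = (
        config.divergence / (1.0 - config.indel_rate)
        if config.indel_rate < 1.0
        else config.divergence
    )
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.genome_length
        mat = _random_codes(rng, L)
        positions = np.flatnonzero(rng.random(L) < event_rate)
        is_indel = rng.random(positions.size) < config.indel_rate
        pieces: list[np.ndarray] = []
        cursor = 0
        pat_offset = 0  # paternal_pos - maternal_pos for upcoming segment
        for p, indel in zip(positions, is_indel):
            p = int(p)
            if p < cursor:
                continue  # consumed by a previous deletion
            if not indel:
                new = (int(mat[p]) + int(rng.integers(1, 4))) % 4
                pieces.append(mat[cursor:p])
                pieces.append(np.array([new], dtype=np.uint8))
                rows.append(
                    (
                        chrom,
                        p,
                        p + 1,
                        p + pat_offset,
                        "SNP",
                        "ACGT"[mat[p]],
                        "ACGT"[new],
                    )
                )
                cursor = p + 1
            else:
                length = int(rng.integers(1, 11))
                if rng.random() < 0.5:  # insertion in the paternal lineage
                    ins = _random_codes(rng, length)
                    pieces.append(mat[cursor:p])
                    pieces.append(ins)
                    rows.append(
                        (chrom, p, p, p + pat_offset, "INS", "", _codes_to_str(ins))
                    )
                    pat_offset += length
                    cursor = p
                    # do not re-site an event at p itself; advance past it
                    pieces.append(mat[p : p + 1])
                    cursor = p + 1
                else:  # deletion from the paternal lineage
                    length = min(length, L - p)
                    pieces.append(mat[cursor:p])
                    rows.append(
                        (
                            chrom,
                            p,
                            p + length,
                            p + pat_offset,
                            "DEL",
                            _codes_to_str(mat[p : p + length]),
                            "",
                        )
                    )
                    pat_offset -= length
                    cursor = p + length
        pieces.append(mat[cursor:])
        pat = np.concatenate(pieces) if pieces else mat
        maternal[chrom] = _codes_to_str(mat)
        paternal[chrom] = _codes_to_str(pat)
    variants = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "end", "pat_pos", "kind", "mat_allele", "pat_allele"],
    )
    return maternal, paternal, TruthTable(variants=variants)


class VariantIndex:
    """Per-chromosome edit lookup between the two parental haplotypes.

    Supports counting edit bases (SNPs count 1, indels their length) within
    an interval of either haplotype, and lifting maternal coordinates to
    paternal ones through the cumulative indel offset.
    """

    def __init__(self, variants: pd.DataFrame):
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, df in variants.groupby("chrom"):
            df = df.sort_values("pos")
            kind = df["kind"].to_numpy()
            size = np.where(
                kind == "SNP",
                1,
                np.maximum(
                    df["mat_allele"].str.len().to_numpy(),
                    df["pat_allele"].str.len().to_numpy(),
                ),
            ).astype(np.int64)
            delta = (
                df["pat_allele"].str.len().to_numpy()
                - df["mat_allele"].str.len().to_numpy()
            )
            self._by_chrom[chrom] = {
                "mat_pos": df["pos"].to_numpy(np.int64),
                "pat_pos": df["pat_pos"].to_numpy(np.int64),
                "size": size,
                "cum_delta": np.cumsum(delta),
            }

    def edits_in(self, haplotype: str, chrom: str, start: int, end: int) -> int:
        idx = self._by_chrom.get(chrom)
        if idx is None:
            return 0
        pos = idx["mat_pos"] if haplotype == MATERNAL else idx["pat_pos"]
        lo, hi = np.searchsorted(pos, [start, end])
        return int(idx["size"][lo:hi].sum())

    def lift(self, chrom: str, pos: int) -> int:
        """Map a maternal coordinate to the homologous paternal coordinate."""
        idx = self._by_chrom.get(chrom)
        if idx is None:
            return pos
        i = np.searchsorted(idx["mat_pos"], pos, side="right")
        offset = int(idx["cum_delta"][i - 1]) if i > 0 else 0
        return pos + offset


# ---------------------------------------------------------------------------
# error injection


def inject_errors(
    codes: np.ndarray,
    rate: float,
    weights: Sequence[float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Apply per-base independent mismatch/insertion/deletion errors.

    Returns the mutated code array and the number of error events.
    """
    if rate <= 0 or codes.size == 0:
        return codes, 0
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size == 0:
        return codes, 0
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    kinds = rng.choice(3, size=hit.size, p=w)
    out = codes.copy()
    sub = hit[kinds == 0]
    out[sub] = (out[sub] + rng.integers(1, 4, size=sub.size)) % 4
    ins = hit[kinds == 1]
    dels = hit[kinds == 2]
    if ins.size == 0 and dels.size == 0:
        return out, int(hit.size)
    keep = np.ones(out.size, dtype=bool)
    keep[dels] = False
    segments: list[np.ndarray] = []
    ins_bases = rng.integers(0, 4, size=ins.size, dtype=np.uint8)
    prev = 0
    for p, b in zip(np.sort(ins), ins_bases):
        segments.append(out[prev:p][keep[prev:p]])
        segments.append(np.array([b], dtype=np.uint8))
        prev = p
    segments.append(out[prev:][keep[prev:]])
    return np.concatenate(segments), int(hit.size)


# ---------------------------------------------------------------------------
# F1 long reads


def simulate_f1_long_reads(
    maternal_genome: dict[str, str],
    paternal_genome: dict[str, str],
    config: SimConfig,
) -> tuple[list[io.FastqRead], TruthTable]:
    """F1 long reads with per-read haplotype-of-origin truth.

    Haplotype chosen uniformly per read; chromosome weighted by length;
    lengths log-normal (sigma=0.5) with the configured mean, truncated at
    1 kb and the chromosome length; per-base errors at ``long_read_error``
    with the configured mismatch:ins:del weights.  Reads are emitted until
    total length reaches ``long_read_depth`` times the diploid genome size.
    """
    if not maternal_genome or not paternal_genome:
        raise ValueError("parental genomes must be non-empty")
    if config.long_read_depth <= 0:
        raise ValueError("long_read_depth must be positive")
    rng = config.rng("long_reads")
    genomes = {MATERNAL: maternal_genome, PATERNAL: paternal_genome}
    encoded = {
        hap: {c: _seq.encode(s) for c, s in g.items()} for hap, g in genomes.items()
    }
    diploid = sum(len(s) for g in genomes.values() for s in g.values())
    target = config.long_read_depth * diploid
    sigma = 0.5
    mu = math.log(config.long_read_mean) - sigma**2 / 2
    reads: list[io.FastqRead] = []
    rows: list[tuple] = []
    total = 0
    i = 0
    while total < target:
        hap = MATERNAL if rng.random() < 0.5 else PATERNAL
        genome = genomes[hap]
        chroms = list(genome)
        lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        L = len(genome[chrom])
        rl = int(rng.lognormal(mu, sigma))
        rl = max(1000, min(rl, L))
        start = int(rng.integers(0, L - rl + 1))
        codes = encoded[hap][chrom][start : start + rl]
        mutated, n_err = inject_errors(
            codes, config.long_read_error, config.error_weights, rng
        )
        read_id = f"read{i:06d}"
        seq = _codes_to_str(mutated)
        reads.append(io.FastqRead(read_id, seq, "I" * len(seq)))
        rows.append((read_id, hap, chrom, start, start + rl, n_err))
        total += len(seq)
        i += 1
    truth = pd.DataFrame(
        rows, columns=["read_id", "haplotype", "chrom", "start", "end", "n_errors"]
    )
    return reads, TruthTable(reads=truth)


# ---------------------------------------------------------------------------
# parental short reads


def simulate_parent_short_reads(
    genome: dict[str, str],
    config: SimConfig,
    parent: str = MATERNAL,
) -> list[io.FastqRead]:
    """Paired-end short reads from one parent.

    The parent is diploid: a second haplotype is derived by planting
    heterozygous SNPs at rate ``within_species_het``, and each fragment
    samples one of the two copies uniformly.  Errors are substitutions at
    ``short_read_error``.  Mate 2 is reverse-complemented.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    rl = config.short_read_length
    for chrom, seq in genome.items():
        if rl > len(seq):
            raise ValueError(f"read length {rl} exceeds {chrom} length {len(seq)}")
    rng = config.rng("short_reads_mat" if parent == MATERNAL else "short_reads_pat")
    reads: list[io.FastqRead] = []
    pair_idx = 0
    for chrom, seq in genome.items():
        codes = _seq.encode(seq)
        L = codes.size
        # second haplotype of this (diploid) parent
        het_pos = np.flatnonzero(rng.random(L) < config.within_species_het)
        alt = codes.copy()
        alt[het_pos] = (alt[het_pos] + rng.integers(1, 4, size=het_pos.size)) % 4
        n_pairs = int(round(config.short_read_depth * L / (2 * rl)))
        insert = np.maximum(
            2 * rl, rng.normal(450, 50, size=n_pairs).astype(np.int64)
        )
        insert = np.minimum(insert, L)
        starts = rng.integers(0, L - insert + 1)
        copy2 = rng.random(n_pairs) < 0.5
        idx1 = starts[:, None] + np.arange(rl)[None, :]
        idx2 = (starts + insert - rl)[:, None] + np.arange(rl)[None, :]
        m1 = np.where(copy2[:, None], alt[idx1], codes[idx1])
        m2 = np.where(copy2[:, None], alt[idx2], codes[idx2])
        m2 = 3 - m2[:, ::-1]  # reverse complement mate 2
        if config.short_read_error > 0:
            for m in (m1, m2):
                hit = rng.random(m.shape) < config.short_read_error
                m[hit] = (m[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        s1 = _matrix_to_strings(m1)
        s2 = _matrix_to_strings(m2)
        qual = "I" * rl
        for a, b in zip(s1, s2):
            reads.append(io.FastqRead(f"{parent[:3].lower()}_pair{pair_idx:07d}/1", a, qual))
            reads.append(io.FastqRead(f"{parent[:3].lower()}_pair{pair_idx:07d}/2", b, qual))
            pair_idx += 1
    return reads


# ---------------------------------------------------------------------------
# Hi-C pairs


def simulate_hic_pairs(
    maternal_genome: dict[str, str],
    paternal_genome: dict[str, str],
    config: SimConfig,
    truth: TruthTable,
) -> tuple[
    list[io.FastqRead],
    list[io.FastqRead],
    dict[str, list[pysam.AlignedSegment]],
    TruthTable,
]:
    """Hi-C read pairs with alignments against both haplotype assemblies.

    Both mates of a pair come from the same haplotype and chromosome, with a
    discretized Pareto (alpha=1) separation capped at the chromosome length.
    A ``junction_rate`` fraction of reads are ligation chimeras carrying the
    embedded DpnII junction GATCGATC followed by decoy sequence from a random
    other locus.  For each mate one primary SAM record per assembly is
    emitted whose AS tag follows the documented contract
    ``score = matches - 4*mismatches`` (clipped at 0) computed over the
    genuine prefix (through the junction GATC for chimeras, soft-clipping the
    decoy): mismatches against the source haplotype are the injected
    sequencing errors; against the other haplotype, errors plus the truth
    edit bases in the covered interval.

    ``truth`` must carry the variant table from :func:`simulate_parent_genomes`.
    Returns (mates1, mates2, {"maternal": sam records, "paternal": ...}, truth).
    """
    if config.hic_n_pairs <= 0:
        raise ValueError("hic_n_pairs must be positive")
    if set(maternal_genome) != set(paternal_genome):
        raise ValueError("parental genomes must share chromosome structure")
    if truth.variants is None:
        raise ValueError("truth.variants from simulate_parent_genomes is required")
    rng = config.rng("hic")
    vindex = VariantIndex(truth.variants)
    rl = config.short_read_length
    genomes = {MATERNAL: maternal_genome, PATERNAL: paternal_genome}
    encoded = {
        hap: {c: _seq.encode(s) for c, s in g.items()} for hap, g in genomes.items()
    }
    junction_codes = _seq.encode(JUNCTION)
    headers = {
        "maternal": io.sam_header(maternal_genome),
        "paternal": io.sam_header(paternal_genome),
    }
    mates1: list[io.FastqRead] = []
    mates2: list[io.FastqRead] = []
    sams: dict[str, list[pysam.AlignedSegment]] = {"maternal": [], "paternal": []}
    rows: list[tuple] = []

    def _decoy(n: int) -> np.ndarray:
        hap = MATERNAL if rng.random() < 0.5 else PATERNAL
        chrom = list(genomes[hap])[rng.integers(0, len(genomes[hap]))]
        arr = encoded[hap][chrom]
        s = int(rng.integers(0, max(1, arr.size - n)))
        piece = arr[s : s + n]
        if piece.size < n:
            piece = np.pad(piece, (0, n - piece.size), constant_values=0)
        return piece

    def _make_mate(hap: str, chrom: str, pos: int) -> tuple[np.ndarray, int, int, bool]:
        """Returns (codes, effective aligned length, n errors in prefix, chimeric)."""
        arr = encoded[hap][chrom]
        chimeric = bool(rng.random() < config.junction_rate)
        if chimeric and rl > 40:
            u = int(rng.integers(20, rl - len(JUNCTION) - 12))
            prefix = arr[pos : pos + u].copy()
            rest = _decoy(rl - u - len(junction_codes))
            codes = np.concatenate([prefix, junction_codes, rest])
            eff = u + 4  # retained prefix ends with the first GATC
        else:
            chimeric = False
            codes = arr[pos : pos + rl].copy()
            eff = rl
        n_err = 0
        if config.hic_read_error > 0:
            hit = np.flatnonzero(rng.random(codes.size) < config.hic_read_error)
            codes[hit] = (codes[hit] + rng.integers(1, 4, size=hit.size)) % 4
            n_err = int((hit < eff).sum())
        return codes, eff, n_err, chimeric

    def _scores(hap: str, chrom: str, pos: int, span: int, eff: int, n_err: int):
        own = max(0, eff - 5 * n_err)
        edits = vindex.edits_in(hap, chrom, pos, pos + span)
        other = max(0, eff - 5 * (n_err + edits))
        if hap == MATERNAL:
            return own, other
        return other, own

    for i in range(config.hic_n_pairs):
        pair_id = f"hic{i:07d}"
        hap = MATERNAL if rng.random() < 0.5 else PATERNAL
        genome = genomes[hap]
        chroms = list(genome)
        lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        L = len(genome[chrom])
        sep = int(1000 / max(rng.random(), 1e-9))  # Pareto(alpha=1), x_m = 1 kb
        sep = min(sep, L - rl)
        p1 = int(rng.integers(0, max(1, L - rl - sep + 1)))
        p2 = min(p1 + sep, L - rl)
        c1, eff1, e1, chim1 = _make_mate(hap, chrom, p1)
        c2, eff2, e2, chim2 = _make_mate(hap, chrom, p2)
        span1 = min(eff1, rl)
        span2 = min(eff2, rl)
        sm1, sp1 = _scores(hap, chrom, p1, span1, eff1, e1)
        sm2, sp2 = _scores(hap, chrom, p2, span2, eff2, e2)
        seq1, seq2 = _codes_to_str(c1), _codes_to_str(c2)
        # mate 2 is sequenced from the opposite strand
        seq2_read = _seq.revcomp(seq2)
        mates1.append(io.FastqRead(pair_id, seq1, "I" * len(seq1)))
        mates2.append(io.FastqRead(pair_id, seq2_read, "I" * len(seq2_read)))
        for asm in ("maternal", "paternal"):
            own = (asm == "maternal") == (hap == MATERNAL)
            if own:
                q1, q2 = p1, p2
            elif hap == MATERNAL:
                q1, q2 = vindex.lift(chrom, p1), vindex.lift(chrom, p2)
            else:  # read from paternal, target maternal: approximate inverse lift
                q1 = p1 - (vindex.lift(chrom, p1) - p1)
                q2 = p2 - (vindex.lift(chrom, p2) - p2)
            s1 = sm1 if asm == "maternal" else sp1
            s2 = sm2 if asm == "maternal" else sp2
            for mate, (seq, eff, q, score) in enumerate(
                [(seq1, eff1, q1, s1), (seq2_read, eff2, q2, s2)]
            ):
                rec = pysam.AlignedSegment(headers[asm])
                rec.query_name = pair_id
                rec.query_sequence = seq
                rec.flag = (
                    0x1
                    | (0x40 if mate == 0 else 0x80)
                    | (0x10 if mate == 1 else 0x20)
                )
                rec.reference_id = headers[asm].get_tid(chrom)
                ref_len = headers[asm].get_reference_length(chrom)
                rec.reference_start = max(0, min(q, ref_len - 1))
                rec.mapping_quality = 60
                clip = len(seq) - eff
                cigar = [(0, eff)] + ([(4, clip)] if clip else [])
                if mate == 1:
                    cigar = cigar[::-1]
                rec.cigartuples = cigar
                rec.set_tag("AS", int(score))
                sams[asm].append(rec)
        rows.append(
            (pair_id, hap, chrom, p1, p2, chim1, chim2, sm1 + sm2, sp1 + sp2)
        )
    truth_pairs = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "haplotype",
            "chrom",
            "pos1",
            "pos2",
            "chimera1",
            "chimera2",
            "score_maternal",
            "score_paternal",
        ],
    )
    return mates1, mates2, sams, TruthTable(hic_pairs=truth_pairs)


# ---------------------------------------------------------------------------
# trio genotypes


def draw_allele_freqs(
    n_sites: int,
    rng: np.random.Generator,
    fixed_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Lineage alt-allele frequencies: a mix of near-fixed interspecies
    differences (sire lineage ~0.02, dam lineage ~0.98) and within-lineage
    polymorphism (independent Beta(0.8, 0.8) draws)."""
    fixed = rng.random(n_sites) < fixed_fraction
    p_sire = np.where(fixed, 0.02, rng.beta(0.8, 0.8, n_sites))
    p_dam = np.where(fixed, 0.98, rng.beta(0.8, 0.8, n_sites))
    return p_sire, p_dam


def simulate_trio_genotypes(
    n_sites: int,
    allele_freqs: tuple[np.ndarray, np.ndarray] | None,
    config: SimConfig,
    n_unrelated_sires: int = 4,
    n_unrelated_dams: int = 1,
) -> tuple[str, TruthTable]:
    """VCF text for a trio plus unrelated candidate parents.

    Parental genotypes are two Bernoulli draws from their lineage's alt
    frequency; the child inherits one allele from each true parent;
    unrelated candidates are drawn from the lineage of the parent they
    impersonate.  Genotyping error flips one randomly chosen allele of a
    genotype with probability ``genotype_error`` (the allele-dropout /
    undersampled-het regime of low-coverage genotyping).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = config.rng("genotypes")
    if allele_freqs is None:
        p_sire, p_dam = draw_allele_freqs(n_sites, rng)
    else:
        p_sire = np.asarray(allele_freqs[0], dtype=float)
        p_dam = np.asarray(allele_freqs[1], dtype=float)
        if p_sire.shape != (n_sites,) or p_dam.shape != (n_sites,):
            raise ValueError("allele_freqs arrays must have length n_sites")
        if ((p_sire < 0) | (p_sire > 1) | (p_dam < 0) | (p_dam > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]; only "
                             "biallelic sites are supported")

    samples = (
        ["sire", "dam", "child"]
        + [f"uSire{j + 1}" for j in range(n_unrelated_sires)]
        + [f"uDam{j + 1}" for j in range(n_unrelated_dams)]
    )
    lineage_p = {}
    true_a1 = {}
    true_a2 = {}
    for s in samples:
        p = p_dam if ("dam" in s.lower()) else p_sire
        if s != "child":
            true_a1[s] = (rng.random(n_sites) < p).astype(np.int8)
            true_a2[s] = (rng.random(n_sites) < p).astype(np.int8)
        lineage_p[s] = p
    pick_s = rng.random(n_sites) < 0.5
    pick_d = rng.random(n_sites) < 0.5
    true_a1["child"] = np.where(pick_s, true_a1["sire"], true_a2["sire"]).astype(np.int8)
    true_a2["child"] = np.where(pick_d, true_a1["dam"], true_a2["dam"]).astype(np.int8)

    obs_a1, obs_a2 = {}, {}
    for s in samples:
        a1, a2 = true_a1[s].copy(), true_a2[s].copy()
        err = rng.random(n_sites) < config.genotype_error
        which = rng.random(n_sites) < 0.5
        flip1 = err & which
        flip2 = err & ~which
        a1[flip1] = 1 - a1[flip1]
        a2[flip2] = 1 - a2[flip2]
        obs_a1[s], obs_a2[s] = a1, a2

    ref, alt = "A", "C"
    contig_len = 10 * (n_sites + 1)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={contig_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    truth_rows = []
    for i in range(n_sites):
        gts = []
        for s in samples:
            lo = min(obs_a1[s][i], obs_a2[s][i])
            hi = max(obs_a1[s][i], obs_a2[s][i])
            gts.append(f"{lo}/{hi}")
            truth_rows.append(
                (i, 10 * (i + 1), s, int(true_a1[s][i]) + int(true_a2[s][i]))
            )
        lines.append(
            f"chr1\t{10 * (i + 1)}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["site", "pos", "sample", "true_alt_count"]
    )
    return "\n".join(lines) + "\n", TruthTable(genotypes=truth)


# ---------------------------------------------------------------------------
# pileups


@dataclass
class PanelMember:
    """One individual in a pileup panel."""

    sample_id: str
    divergence: float  # per-base probability of a homozygous non-ref site
    mean_depth: float = 12.0
    het: float | None = None  # defaults to config.within_species_het


def simulate_pileups(
    reference_genome: dict[str, str],
    panel_spec: Sequence[PanelMember],
    config: SimConfig,
    seq_error: float = 0.002,
    divergence_tracks: dict[str, dict[str, np.ndarray]] | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Six-column pileup text per panel individual over a shared reference.

    Per position each individual is HOM_ALT with probability equal to its
    divergence from the reference, HET with its heterozygosity, else REF;
    depth is Poisson around the member's mean; the base column is consistent
    with the genotype (alt fraction ~1, ~0.5, ~``seq_error``).

    ``divergence_tracks`` optionally overrides the scalar divergence with a
    per-chromosome per-base array (used to plant introgressed segments).
    """
    if not panel_spec:
        raise ValueError("panel_spec must contain at least one individual")
    rng = config.rng("pileups")
    pileups: dict[str, str] = {}
    truth_rows = []
    alt_of = {0: "C", 1: "G", 2: "T", 3: "A"}
    for member in panel_spec:
        het = config.within_species_het if member.het is None else member.het
        lines: list[str] = []
        for chrom, seq in reference_genome.items():
            codes = _seq.encode(seq)
            L = codes.size
            if divergence_tracks and member.sample_id in divergence_tracks:
                d = divergence_tracks[member.sample_id][chrom]
            else:
                d = np.full(L, member.divergence)
            u = rng.random(L)
            hom = u < d
            het_mask = (~hom) & (u < d + het)
            depth = rng.poisson(member.mean_depth, L)
            n_alt = np.zeros(L, dtype=np.int64)
            n_alt[hom] = depth[hom] - rng.binomial(depth[hom], seq_error)
            n_alt[het_mask] = rng.binomial(depth[het_mask], 0.5)
            ref_only = ~(hom | het_mask)
            n_alt[ref_only] = rng.binomial(depth[ref_only], seq_error)
            n_ref = depth - n_alt
            refs = [("ACGT"[c] if c < 4 else "N") for c in codes]
            alts = [alt_of[int(c) % 4] for c in codes]
            rows = [
                f"{chrom}\t{p + 1}\t{refs[p]}\t{depth[p]}\t"
                f"{'.' * n_ref[p]}{alts[p] * n_alt[p]}\t{'I' * depth[p]}"
                for p in range(L)
            ]
            lines.extend(rows)
            geno = np.where(hom, "HOM_ALT", np.where(het_mask, "HET", "REF"))
            var_pos = np.flatnonzero(geno != "REF")
            for p in var_pos:
                truth_rows.append(
                    (member.sample_id, chrom, int(p), geno[p])
                )
        pileups[member.sample_id] = "\n".join(lines) + "\n"
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "chrom", "pos", "genotype"]
    )
    return pileups, TruthTable(pileup_sites=truth)


def make_phasing_fixture(
    config: SimConfig,
    segment: tuple[str, int, int] | None = ("chr1", 150_000, 300_000),
    reciprocal: bool = False,
    own_divergence: float = 0.001,
    other_divergence: float = 0.006,
    n_per_panel: int = 3,
    mean_depth: float = 12.0,
) -> dict[str, dict[str, list]]:
    """Window SNP rates for species panels against both haplotype assemblies.

    Emulates aligning ``n_per_panel`` yaks and cattle to the maternal (yak)
    and paternal (cattle) assembly: each individual diverges from its own
    species' assembly at ``own_divergence`` and from the other assembly at
    ``other_divergence``.  Within ``segment`` (coordinates on the shared
    window grid) the maternal assembly is made cattle-like — the divergence
    tracks swap there; with ``reciprocal`` the paternal assembly swaps over
    the same segment too (a haplotype switch rather than introgression).

    Runs the full pileup -> site call -> window rate path and returns
    ``{"maternal": rates_by_individual, "paternal": ...}`` ready for
    :func:`triobin.phasing.compare_panels` with the assembly's own species
    as panel A.
    """
    from . import phasing

    # shared collinear coordinate frame for both assemblies
    genome = simulate_parent_genomes(config)[0]
    cattle = [f"cattle{i + 1}" for i in range(n_per_panel)]
    yaks = [f"yak{i + 1}" for i in range(n_per_panel)]

    def _tracks(assembly: str, swapped: bool) -> dict[str, dict[str, np.ndarray]]:
        own = yaks if assembly == "maternal" else cattle
        other = cattle if assembly == "maternal" else yaks
        tracks: dict[str, dict[str, np.ndarray]] = {}
        for sid in own + other:
            base = own_divergence if sid in own else other_divergence
            flipped = other_divergence if sid in own else own_divergence
            per_chrom = {}
            for chrom, seq in genome.items():
                d = np.full(len(seq), base)
                if swapped and segment and segment[0] == chrom:
                    d[segment[1] : segment[2]] = flipped
                per_chrom[chrom] = d
            tracks[sid] = per_chrom
        return tracks

    out: dict[str, dict[str, list]] = {}
    for assembly in ("maternal", "paternal"):
        swapped = segment is not None and (assembly == "maternal" or reciprocal)
        members = [
            PanelMember(sid, 0.0, mean_depth) for sid in cattle + yaks
        ]
        pileups, _ = simulate_pileups(
            genome,
            members,
            config,
            divergence_tracks=_tracks(assembly, swapped),
        )
        out[assembly] = {
            sid: phasing.pileup_to_window_rates(
                list(io.parse_pileup(text.splitlines()))
            )
            for sid, text in pileups.items()
        }
    return out


# ---------------------------------------------------------------------------
# gap / telomere fixtures


@dataclass
class GapFixtureConfig:
    """Planted closure classes per gap for each of two target assemblies.

    ``statuses_a``/``statuses_b`` list, per reference gap, the intended
    ClosureCall status against targets A and B: CLOSED, TRANS_SCAFFOLD,
    OPEN (flanks 150 kb apart), OPEN_GAP (an intervening N-run), UNPLACED.
    """

    statuses_a: tuple[str, ...] = (
        "CLOSED",
        "CLOSED",
        "TRANS_SCAFFOLD",
        "OPEN",
        "OPEN_GAP",
        "UNPLACED",
    )
    statuses_b: tuple[str, ...] = (
        "CLOSED",
        "OPEN",
        "TRANS_SCAFFOLD",
        "CLOSED",
        "CLOSED",
        "CLOSED",
    )
    flank: int = 500
    gap_len: int = 50
    spacer: int = 600  # clear sequence between one gap's flank and the next gap
    closed_sep: int = 2_000
    open_sep: int = 150_000
    n_repeat_overlaps: int = 4

    def __post_init__(self) -> None:
        if len(self.statuses_a) != len(self.statuses_b):
            raise ValueError("statuses_a and statuses_b must align per gap")
        if self.flank > self.spacer:
            raise ValueError(
                f"flank length {self.flank} exceeds inter-gap spacing {self.spacer}"
            )


@dataclass
class GapFixture:
    reference: dict[str, str]
    targets: dict[str, dict[str, str]]  # "A"/"B" -> assembly
    flank_sams: dict[str, list[pysam.AlignedSegment]]
    flank_headers: dict[str, pysam.AlignmentHeader]
    repeats: list[tuple[str, int, int, str]]  # BED rows on the reference
    gap_flanks: dict[str, tuple[tuple[str, int, int], tuple[str, int, int]]]
    truth: TruthTable


def make_gap_fixture(config: SimConfig, gap_config: GapFixtureConfig | None = None) -> GapFixture:
    """Reference with N-gaps plus two target assemblies of designed closure status.

    The reference chromosome carries, per gap, 500-bp unique flanks around an
    N-run.  Each target assembly re-embeds the flank pairs at separations and
    scaffold arrangements that force the intended status; flank alignment SAM
    records are emitted consistent with that construction (perfect matches,
    AS = flank length).  Repeat intervals (L1/BovB labels) are planted over a
    subset of 5' flanks on the reference.
    """
    gc = gap_config or GapFixtureConfig()
    rng = config.rng("gaps")
    n_gaps = len(gc.statuses_a)
    ref_parts: list[str] = []
    flank_seqs: dict[str, str] = {}
    gap_flanks: dict[str, tuple] = {}
    truth_rows = []
    pos = 0
    ref_chrom = "ref1"
    for g in range(n_gaps):
        gap_id = f"gap{g + 1}"
        left = _codes_to_str(_random_codes(rng, gc.flank))
        right = _codes_to_str(_random_codes(rng, gc.flank))
        spacer = _codes_to_str(_random_codes(rng, gc.spacer))
        ref_parts.extend([spacer, left, "N" * gc.gap_len, right])
        pos += gc.spacer
        l_iv = (ref_chrom, pos, pos + gc.flank)
        pos += gc.flank + gc.gap_len
        r_iv = (ref_chrom, pos, pos + gc.flank)
        pos += gc.flank
        flank_seqs[f"{gap_id}_5p"] = left
        flank_seqs[f"{gap_id}_3p"] = right
        gap_flanks[gap_id] = (l_iv, r_iv)
    reference = {ref_chrom: "".join(ref_parts)}

    targets: dict[str, dict[str, str]] = {}
    sams: dict[str, list[pysam.AlignedSegment]] = {}
    headers: dict[str, pysam.AlignmentHeader] = {}
    for label, statuses in (("A", gc.statuses_a), ("B", gc.statuses_b)):
        assembly: dict[str, str] = {}
        placements: list[tuple[str, str, int, int]] = []  # flank, scaf, start, AS
        for g, status in enumerate(statuses):
            gap_id = f"gap{g + 1}"
            left = flank_seqs[f"{gap_id}_5p"]
            right = flank_seqs[f"{gap_id}_3p"]
            scaf = f"{label.lower()}_scaf{g + 1}"
            if status == "CLOSED":
                fill = _codes_to_str(_random_codes(rng, gc.closed_sep))
                assembly[scaf] = left + fill + right
                placements.append((f"{gap_id}_5p", scaf, 0, gc.flank))
                placements.append(
                    (f"{gap_id}_3p", scaf, gc.flank + gc.closed_sep, gc.flank)
                )
            elif status == "OPEN":
                fill = _codes_to_str(_random_codes(rng, gc.open_sep))
                assembly[scaf] = left + fill + right
                placements.append((f"{gap_id}_5p", scaf, 0, gc.flank))
                placements.append(
                    (f"{gap_id}_3p", scaf, gc.flank + gc.open_sep, gc.flank)
                )
            elif status == "OPEN_GAP":
                fill1 = _codes_to_str(_random_codes(rng, 1000))
                fill2 = _codes_to_str(_random_codes(rng, 1000))
                assembly[scaf] = left + fill1 + "N" * 100 + fill2 + right
                placements.append((f"{gap_id}_5p", scaf, 0, gc.flank))
                placements.append(
                    (f"{gap_id}_3p", scaf, gc.flank + 2100, gc.flank)
                )
            elif status == "TRANS_SCAFFOLD":
                scaf2 = scaf + "b"
                pad1 = _codes_to_str(_random_codes(rng, 300))
                pad2 = _codes_to_str(_random_codes(rng, 300))
                assembly[scaf] = left + pad1
                assembly[scaf2] = pad2 + right
                placements.append((f"{gap_id}_5p", scaf, 0, gc.flank))
                placements.append((f"{gap_id}_3p", scaf2, 300, gc.flank))
            elif status == "UNPLACED":
                pad = _codes_to_str(_random_codes(rng, 300))
                assembly[scaf] = left + pad
                placements.append((f"{gap_id}_5p", scaf, 0, gc.flank))
            else:
                raise ValueError(f"unknown planted status {status!r}")
            truth_rows.append(
                (gap_id, label, "OPEN" if status == "OPEN_GAP" else status)
            )
        header = io.sam_header(assembly)
        records = []
        for flank_name, scaf, start, score in placements:
            rec = pysam.AlignedSegment(header)
            rec.query_name = flank_name
            rec.query_sequence = flank_seqs[flank_name]
            rec.flag = 0
            rec.reference_id = header.get_tid(scaf)
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(flank_seqs[flank_name]))]
            rec.set_tag("AS", score)
            records.append(rec)
        targets[label] = assembly
        sams[label] = records
        headers[label] = header

    # plant repeats over the first n 5' flanks on the reference
    repeats = []
    names = ["L1", "BovB"]
    for g in range(min(gc.n_repeat_overlaps, n_gaps)):
        l_iv = gap_flanks[f"gap{g + 1}"][0]
        mid = (l_iv[1] + l_iv[2]) // 2
        repeats.append((ref_chrom, mid - 50, mid + 50, names[g % len(names)]))

    truth = pd.DataFrame(truth_rows, columns=["gap_id", "target", "status"])
    return GapFixture(
        reference=reference,
        targets=targets,
        flank_sams=sams,
        flank_headers=headers,
        repeats=repeats,
        gap_flanks=gap_flanks,
        truth=TruthTable(gaps=truth),
    )


def make_telomere_fixture(
    config: SimConfig,
    repeat_counts: Sequence[int] = (8, 6, 5, 4, 1, 0),
    length: int = 5_000,
) -> dict[str, str]:
    """Toy sequences whose last kilobase contains the given number of
    tandem TTAGGG repeats (planted at the very end)."""
    rng = config.rng("telomeres")
    out = {}
    for i, n in enumerate(repeat_counts):
        body = _codes_to_str(_random_codes(rng, length - 6 * n))
        # scrub chance occurrences from the terminal kilobase of the body
        tail_start = max(0, length - 6 * n - 1000)
        body = body[:tail_start] + body[tail_start:].replace("TTAGGG", "TTAGGC")
        out[f"seq{i + 1}_n{n}"] = body + "TTAGGG" * n
    return out
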