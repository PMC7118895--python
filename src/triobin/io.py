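"""Shared format readers and writers.

Internal convention: coordinates are 0-based half-open everywhere in memory;
1-based coordinates appear only at VCF/pileup/SAM serialization boundaries.
Sequence sets are plain ``{name: sequence}`` dicts.  FASTA/FASTQ parsing goes
through Biopython; SAM through pysam (plain-text SAM, no BAM requirement).
"""

from __future__ import annotations

import sys
from typing import Iterable, Iterator, NamedTuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqRead(NamedTuple):
    """A lightweight FASTQ record (qualities as an ASCII phred+33 string)."""

    id: str
    seq: str
    qual: str


class PileupRecord(NamedTuple):
    """One line of six-column pileup text (pos is 1-based as printed)."""

    chrom: str
    pos: int
    ref: str
    depth: int
    bases: str
    quals: str


def log(stage: str, message: str) -> None:
    """Stage-tagged logging to standard error."""
    print(f"[{stage}] {message}", file=sys.stderr)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> Iterator[FastqRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield FastqRead(rec.id, str(rec.seq), qual)


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# SAM


def sam_header(sequences: dict[str, str] | dict[str, int]) -> pysam.AlignmentHeader:
    """Build a SAM header from a sequence dict or a {name: length} dict."""
    lengths = {
        name: (len(v) if isinstance(v, str) else int(v))
        for name, v in sequences.items()
    }
    return pysam.AlignmentHeader.from_references(
        list(lengths), list(lengths.values())
    )


def write_sam(path, header: pysam.AlignmentHeader, records) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def read_sam(path) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh


# ---------------------------------------------------------------------------
# VCF (written as text; read back through pysam)


def write_vcf(path, text: str) -> None:
    with open(path, "w") as fh:
        fh.write(text)


def open_vcf(path) -> pysam.VariantFile:
    return pysam.VariantFile(str(path))


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED as (chrom, start, end, name) tuples; malformed lines skipped."""
    out = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError):
                log("bed", f"skipping malformed BED line {n}: {line!r}")
                continue
            name = fields[3] if len(fields) > 3 else "."
            out.append((chrom, start, end, name))
    return out


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# Pileup text (six-column samtools mpileup dialect)


def parse_pileup(lines: Iterable[str]) -> Iterator[PileupRecord]:
    for line in lines:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        chrom, pos, ref, depth = fields[0], int(fields[1]), fields[2], int(fields[3])
        bases = fields[4] if len(fields) > 4 else ""
        quals = fields[5] if len(fields) > 5 else ""
        yield PileupRecord(chrom, pos, ref, depth, bases, quals)


def read_pileup(path) -> Iterator[PileupRecord]:
    with open(path) as fh:
        yield from parse_pileup(fh)


def pileup_base_counts(record: PileupRecord) -> tuple[int, int]:
    """Count (reference, non-reference) base calls in a pileup base column.

    Handles the mpileup dialect: ``.``/``,`` are reference matches, ACGT
    letters are substitutions, ``^X`` (start marker + mapping quality) and
    ``$`` are stripped, ``+n<seq>``/``-n<seq>`` indel annotations are skipped,
    ``*`` deletion placeholders and ``>``/``<`` reference skips count as
    neither.  Raises ValueError on a malformed column.
    """
    bases = record.bases
    # fast path: plain match/substitution columns (no markers or indels)
    if not any(c in bases for c in "^$+-*><"):
        n_ref = bases.count(".") + bases.count(",")
        n_other = sum(bases.count(c) for c in "ACGTNacgtn")
        if n_ref + n_other == len(bases):
            return n_ref, n_other
    n_ref = n_alt = 0
    i = 0
    L = len(bases)
    while i < L:
        c = bases[i]
        if c in ".,":
            n_ref += 1
            i += 1
        elif c in "ACGTNacgtn":
            n_alt += 1
            i += 1
        elif c == "^":
            i += 2  # skip mapping-quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < L and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(f"malformed indel annotation in {bases!r}")
            i = j + int(bases[i + 1 : j])
        elif c in "*><":
            i += 1
        else:
            raise ValueError(f"unexpected pileup character {c!r} in {bases!r}")
    return n_ref, n_alt
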