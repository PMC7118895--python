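"""Assembly gap-closure classification and telomere detection.

A reference gap (maximal N-run) is considered closed by a target assembly
when the 500-bp sequences flanking the gap align to the same target
scaffold, within 100 kb of each other, with no target-assembly gap in the
spanned interval.  Flanks on different scaffolds indicate a possible
scaffolding discrepancy (trans-scaffold); gap-flank regions are intersected
with repeat annotations to ask what sequence terminates broken contigs.
Chromosome ends are called telomeric when the vertebrate telomere hexamer
TTAGGG occurs at least five times in the final kilobase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats

from . import io

CLOSED = "CLOSED"
TRANS_SCAFFOLD = "TRANS_SCAFFOLD"
OPEN = "OPEN"
UNPLACED = "UNPLACED"

MAX_CLOSURE_DIST = 100_000
TELOMERE_MOTIF = "TTAGGG"


@dataclass
class GapRecord:
    chrom: str
    start: int  # 0-based half-open N-run interval
    end: int
    gap_id: str


@dataclass
class FlankPair:
    """Extracted flank intervals for one gap (0-based half-open)."""

    gap_id: str
    five_prime: tuple[str, int, int]
    three_prime: tuple[str, int, int]
    truncated_5p: bool = False
    truncated_3p: bool = False
    overlaps_adjacent_gap: bool = False


@dataclass
class ClosureCall:
    gap_id: str
    status: str
    scaffolds: tuple[str, ...]
    separation: int | None  # inner-end distance when on one scaffold
    orientation_ok: bool = True


@dataclass
class TelomereCall:
    seq_id: str
    count: int
    is_telomeric: bool
    truncated_window: bool = False


# ---------------------------------------------------------------------------
# gap inventory and flanks


def find_assembly_gaps(
    sequences: dict[str, str], min_run: int = 10
) -> list[GapRecord]:
    """All maximal N-runs of length >= min_run, case-insensitive."""
    out: list[GapRecord] = []
    i = 0
    for chrom in sequences:
        seq = sequences[chrom].upper()
        pos = 0
        while True:
            start = seq.find("N", pos)
            if start < 0:
                break
            end = start
            while end < len(seq) and seq[end] == "N":
                end += 1
            if end - start >= min_run:
                i += 1
                out.append(GapRecord(chrom, start, end, f"gap{i}"))
            pos = end
    return out


def extract_gap_flanks(
    reference: dict[str, str],
    gaps: Sequence[GapRecord],
    flank: int = 500,
) -> tuple[list[FlankPair], dict[str, str]]:
    """The ``flank`` bp immediately before and after each N-run.

    Returns (flank interval pairs, {"<gap_id>_5p"/"_3p": sequence}).  Flanks
    running off a sequence end are truncated and flagged; flanks overlapping
    an adjacent gap are emitted with an overlap flag.
    """
    n_by_chrom = {c: [(g.start, g.end) for g in gaps if g.chrom == c] for c in reference}
    pairs: list[FlankPair] = []
    seqs: dict[str, str] = {}
    for g in gaps:
        L = len(reference[g.chrom])
        l_start = max(0, g.start - flank)
        r_end = min(L, g.end + flank)
        overlap = any(
            (s < g.start and e > l_start) or (s < r_end and e > g.end)
            for s, e in n_by_chrom[g.chrom]
            if (s, e) != (g.start, g.end)
        )
        pair = FlankPair(
            gap_id=g.gap_id,
            five_prime=(g.chrom, l_start, g.start),
            three_prime=(g.chrom, g.end, r_end),
            truncated_5p=g.start - l_start < flank,
            truncated_3p=r_end - g.end < flank,
            overlaps_adjacent_gap=overlap,
        )
        if pair.truncated_5p or pair.truncated_3p:
            io.log("gaps", f"{g.gap_id}: flank truncated at sequence end")
        pairs.append(pair)
        seqs[f"{g.gap_id}_5p"] = reference[g.chrom][l_start : g.start]
        seqs[f"{g.gap_id}_3p"] = reference[g.chrom][g.end : r_end]
    return pairs, seqs


# ---------------------------------------------------------------------------
# closure classification


def _primary_alignments(
    alignments: Iterable[pysam.AlignedSegment],
) -> dict[str, pysam.AlignedSegment]:
    primary: dict[str, pysam.AlignedSegment] = {}
    for rec in alignments:
        if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
            continue
        if rec.query_name in primary:
            raise ValueError(f"multiple primary alignments for {rec.query_name}")
        primary[rec.query_name] = rec
    return primary


def classify_gap_closure(
    flank_alignments: Iterable[pysam.AlignedSegment],
    target_gaps: Sequence[GapRecord],
    gap_ids: Sequence[str] | None = None,
    max_dist: int = MAX_CLOSURE_DIST,
) -> list[ClosureCall]:
    """Closure status of each reference gap against one target assembly.

    CLOSED requires both flanks on one scaffold, inner-end separation
    <= max_dist, no target N-run overlapping the spanned interval, and
    concordant orientation (both flanks on one strand, ordered accordingly);
    discordant orientation is logged and classified OPEN.  Both flanks on
    different scaffolds is TRANS_SCAFFOLD; a missing primary alignment for
    either flank is UNPLACED.
    """
    primary = _primary_alignments(flank_alignments)
    if gap_ids is None:
        gap_ids = sorted(
            {n.rsplit("_", 1)[0] for n in primary}, key=lambda s: (len(s), s)
        )
    gap_trees: dict[str, IntervalTree] = {}
    for g in target_gaps:
        gap_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    calls: list[ClosureCall] = []
    for gid in gap_ids:
        a5 = primary.get(f"{gid}_5p")
        a3 = primary.get(f"{gid}_3p")
        if a5 is None or a3 is None:
            scafs = tuple(
                a.reference_name for a in (a5, a3) if a is not None
            )
            calls.append(ClosureCall(gid, UNPLACED, scafs, None))
            continue
        if a5.reference_name != a3.reference_name:
            calls.append(
                ClosureCall(
                    gid, TRANS_SCAFFOLD, (a5.reference_name, a3.reference_name), None
                )
            )
            continue
        scaf = a5.reference_name
        left, right = sorted(
            (a5, a3), key=lambda a: (a.reference_start, a.reference_end)
        )
        sep = max(0, right.reference_start - left.reference_end)
        same_strand = a5.is_reverse == a3.is_reverse
        ordered_ok = (
            (not a5.is_reverse and a5.reference_start <= a3.reference_start)
            or (a5.is_reverse and a3.reference_start <= a5.reference_start)
        )
        orientation_ok = same_strand and ordered_ok
        span_lo, span_hi = left.reference_end, right.reference_start
        intervening = (
            span_hi > span_lo
            and scaf in gap_trees
            and bool(gap_trees[scaf].overlap(span_lo, span_hi))
        )
        if sep <= max_dist and not intervening and orientation_ok:
            status = CLOSED
        else:
            status = OPEN
            if not orientation_ok:
                io.log("gaps", f"{gid}: discordant flank orientation on {scaf}")
        calls.append(ClosureCall(gid, status, (scaf,), sep, orientation_ok))
    return calls


def compare_closures(
    calls_a: Sequence[ClosureCall], calls_b: Sequence[ClosureCall]
) -> pd.DataFrame:
    """Cross-tabulate closure status per gap across two target assemblies.

    The returned frame has one row per status in A and one column per
    status in B; ``.attrs['discordant_closed']`` lists gaps closed in
    exactly one assembly.  Gap inventories must match.
    """
    by_a = {c.gap_id: c.status for c in calls_a}
    by_b = {c.gap_id: c.status for c in calls_b}
    if set(by_a) != set(by_b):
        raise ValueError("gap inventories of the two call lists differ")
    statuses = [CLOSED, TRANS_SCAFFOLD, OPEN, UNPLACED]
    table = pd.DataFrame(0, index=statuses, columns=statuses)
    for gid, sa in by_a.items():
        table.loc[sa, by_b[gid]] += 1
    table.attrs["discordant_closed"] = sorted(
        gid
        for gid in by_a
        if (by_a[gid] == CLOSED) != (by_b[gid] == CLOSED)
    )
    return table


# ---------------------------------------------------------------------------
# repeat intersection


def intersect_repeats(
    intervals: Iterable[tuple[str, int, int] | tuple[str, int, int, str]],
    repeats: Iterable[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Count repeat elements (by BED name) overlapping each interval.

    Intervals and BED rows are 0-based half-open; overlap means at least one
    shared base, so an exactly abutting repeat does not count.  Returns one
    row per (interval, repeat class) with the overlap count.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in repeats:
        if end <= start:
            io.log("repeats", f"skipping empty repeat interval {chrom}:{start}-{end}")
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    rows = []
    for iv in intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        label = iv[3] if len(iv) > 3 else f"{chrom}:{start}-{end}"
        hits: dict[str, int] = {}
        if chrom in trees and end > start:
            for hit in trees[chrom].overlap(start, end):
                hits[hit.data] = hits.get(hit.data, 0) + 1
        if hits:
            for name, n in sorted(hits.items()):
                rows.append((label, chrom, start, end, name, n))
        else:
            rows.append((label, chrom, start, end, ".", 0))
    return pd.DataFrame(
        rows, columns=["interval", "chrom", "start", "end", "repeat_class", "count"]
    )


# ---------------------------------------------------------------------------
# telomeres


def _count_occurrences(text: str, motif: str) -> int:
    """Possibly-overlapping exact occurrences of motif in text."""
    n = 0
    i = text.find(motif)
    while i >= 0:
        n += 1
        i = text.find(motif, i + 1)
    return n


def find_telomeres(
    sequences: dict[str, str],
    motif: str = TELOMERE_MOTIF,
    window: int = 1_000,
    min_count: int = 5,
) -> list[TelomereCall]:
    """Telomere calls from motif counts in each sequence's terminal window.

    Counts possibly-overlapping exact occurrences of the motif in the final
    ``window`` bp (TTAGGG cannot overlap itself, so this equals
    non-overlapping counting for the default motif).  Sequences shorter than
    the window are counted over their full length and flagged.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    calls = []
    for seq_id, seq in sequences.items():
        truncated = len(seq) < window
        tail = seq[-window:].upper()
        n = _count_occurrences(tail, motif.upper())
        calls.append(TelomereCall(seq_id, n, n >= min_count, truncated))
    return calls


def telomere_null_pvalue(
    count: int, motif_length: int = 6, window: int = 1_000
) -> float:
    """Tail probability of >= count motif hits in an i.i.d. uniform window.

    Poisson approximation with lambda = (window - motif_length + 1) *
    4**(-motif_length): each of the window's motif-sized positions matches a
    fixed motif with probability 4^-m, matches are rare and nearly
    independent for a non-self-overlapping motif.  Cross-checkable by Monte
    Carlo over random sequences.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return 1.0
    lam = (window - motif_length + 1) * 4.0 ** (-motif_length)
    return float(stats.poisson.sf(count - 1, lam))


def telomere_null_montecarlo(
    count: int,
    n_windows: int,
    rng,
    motif: str = TELOMERE_MOTIF,
    window: int = 1_000,
    batch: int = 200_000,
) -> float:
    """Monte Carlo estimate of P(>= count motif hits) in a uniform window.

    Draws ``n_windows`` i.i.d. uniform-base windows and counts exact
    (possibly overlapping) motif occurrences directly on the simulated
    sequence — an oracle independent of the Poisson closed form.
    """
    import numpy as np

    from . import _seq

    m = _seq.encode(motif.upper())
    if (m > 3).any():
        raise ValueError("motif must be over ACGT")
    k = m.size
    span = window - k + 1
    # pack bases into trinucleotide codes so a hexamer match is two equality
    # tests instead of six (general k handled by a per-base tail loop)
    n_tri = k // 3
    tri_codes = [int(m[3 * t]) * 16 + int(m[3 * t + 1]) * 4 + int(m[3 * t + 2]) for t in range(n_tri)]
    tail = range(3 * n_tri, k)
    hits = 0
    remaining = n_windows
    scratch = None
    while remaining > 0:
        b = min(batch, remaining)
        # bytes are uniform over 0..255, so & 3 is uniform over the 4 bases
        seq = np.frombuffer(rng.bytes(b * window), dtype=np.uint8).reshape(b, window)
        seq = seq & np.uint8(3)
        if n_tri:
            # trinucleotide codes fit in uint8 (max 63); build in place
            if scratch is None or scratch.shape[0] != b:
                scratch = np.empty((b, window - 2), dtype=np.uint8)
            tri = np.left_shift(seq[:, : window - 2], 4, out=scratch)
            tri |= seq[:, 1 : window - 1] << np.uint8(2)
            tri |= seq[:, 2:]
            match = tri[:, :span] == np.uint8(tri_codes[0])
            for t in range(1, n_tri):
                match &= tri[:, 3 * t : span + 3 * t] == np.uint8(tri_codes[t])
        else:
            match = np.ones((b, span), dtype=bool)
        for j in tail:
            match &= seq[:, j : span + j] == m[j]
        hits += int((match.sum(axis=1) >= count).sum())
        remaining -= b
    return hits / n_windows
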