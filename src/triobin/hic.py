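"""Hi-C read-pair preprocessing and haplotype assignment.

Reads are trimmed at the DpnII ligation junction GATCGATC (the chimera
created at proximity-ligation points), aligned to both haplotype assemblies
upstream, and each pair is assigned to the haplotype with the better summed
alignment score (AS tag), or to both when the scores are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pysam

from . import io

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"
BOTH = "BOTH"

JUNCTION = "GATCGATC"


@dataclass
class HiCPairCall:
    pair_id: str
    score_maternal: int
    score_paternal: int
    call: str


def trim_to_junction(read: io.FastqRead) -> io.FastqRead:
    """Truncate a read at the first DpnII ligation junction.

    The retained prefix ends with the first GATC of the junction (the
    genuine restriction site of the first fragment); qualities are truncated
    in step.  Reads without the junction are returned unchanged.
    """
    i = read.seq.find(JUNCTION)
    if i < 0:
        return read
    keep = i + 4
    return io.FastqRead(read.id, read.seq[:keep], read.qual[:keep])


def pair_score(alignments: Iterable[pysam.AlignedSegment]) -> int:
    """Summed AS over the primary alignments of a pair against one assembly.

    Secondary and supplementary records are ignored; an unmapped or missing
    mate contributes 0.  Exact duplicate records are tolerated (idempotent);
    two primary records with different scores for one mate is malformed input.
    """
    seen: dict[bool, int] = {}
    for rec in alignments:
        if rec.is_secondary or rec.is_supplementary:
            continue
        if rec.is_unmapped:
            continue
        mate2 = rec.is_read2
        score = int(rec.get_tag("AS")) if rec.has_tag("AS") else 0
        if mate2 in seen and seen[mate2] != score:
            raise ValueError(
                f"conflicting primary records for mate {2 if mate2 else 1} of "
                f"{rec.query_name}"
            )
        seen[mate2] = score
    return sum(seen.values())


def classify_pair(score_maternal: int, score_paternal: int, margin: int = 0) -> str:
    """MATERNAL/PATERNAL if one assembly scores better by more than
    ``margin``, else BOTH (aligned equally well; used to scaffold both)."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if score_maternal - score_paternal > margin:
        return MATERNAL
    if score_paternal - score_maternal > margin:
        return PATERNAL
    return BOTH


def _scores_by_pair(records: Iterable[pysam.AlignedSegment]) -> dict[str, int]:
    """Group a name-sorted or unsorted SAM stream by pair id and score each."""
    grouped: dict[str, dict[bool, int]] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
            continue
        mates = grouped.setdefault(rec.query_name, {})
        mate2 = rec.is_read2
        score = int(rec.get_tag("AS")) if rec.has_tag("AS") else 0
        if mate2 in mates and mates[mate2] != score:
            raise ValueError(
                f"conflicting primary records for mate {2 if mate2 else 1} of "
                f"{rec.query_name}"
            )
        mates[mate2] = score
    return {name: sum(m.values()) for name, m in grouped.items()}


def partition_hic(
    sam_maternal: Iterable[pysam.AlignedSegment],
    sam_paternal: Iterable[pysam.AlignedSegment],
    margin: int = 0,
) -> tuple[dict[str, set[str]], list[HiCPairCall], dict[str, int]]:
    """Assign every Hi-C pair to maternal, paternal, or both.

    Pairs present in only one stream are counted, logged, and scored with 0
    on the missing side.  Returns ({call: pair-id set}, calls, counts).
    """
    mat_scores = _scores_by_pair(sam_maternal)
    pat_scores = _scores_by_pair(sam_paternal)
    all_ids = set(mat_scores) | set(pat_scores)
    one_sided = (set(mat_scores) ^ set(pat_scores)) & all_ids
    if one_sided:
        io.log("bin-hic", f"{len(one_sided)} pair(s) present in one stream only")
    sets: dict[str, set[str]] = {MATERNAL: set(), PATERNAL: set(), BOTH: set()}
    calls = []
    for pid in sorted(all_ids):
        sm = mat_scores.get(pid, 0)
        sp = pat_scores.get(pid, 0)
        call = classify_pair(sm, sp, margin=margin)
        sets[call].add(pid)
        calls.append(HiCPairCall(pid, sm, sp, call))
    counts = {
        "n_pairs": len(all_ids),
        "n_maternal": len(sets[MATERNAL]),
        "n_paternal": len(sets[PATERNAL]),
        "n_both": len(sets[BOTH]),
        "n_one_sided": len(one_sided),
    }
    return sets, calls, counts
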