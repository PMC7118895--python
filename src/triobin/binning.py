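"""Long-read haplotype binning by parent-unique marker k-mers.

Each read is scanned for canonical k-mer windows present in the maternal or
paternal marker set; the read goes to the bin with the strictly greater hit
count (optionally normalized by marker-set size), ties and zero-hit reads
remain unclassified.  Reads with no parental marker carry no haplotype
information and are dropped from downstream assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import _seq, io
from .kmers import MATERNAL, PATERNAL, MarkerSet

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class ReadBinCall:
    read_id: str
    read_length: int
    maternal_hits: int
    paternal_hits: int
    bin: str


@dataclass
class BinningReport:
    """Aggregate binning statistics.

    ``fraction_of_total_length_classified`` is classified bp (maternal +
    paternal bins) over total bp; ``fraction_of_total_length_with_marker``
    counts reads with >= 1 marker hit of either kind, the quantity behind
    the "reads that can be sorted at all" statistic.
    """

    n_reads: dict[str, int]
    bp: dict[str, int]
    fraction_of_total_length_classified: float
    fraction_of_total_length_with_marker: float
    coverage_per_haplotype: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (b, self.n_reads.get(b, 0), self.bp.get(b, 0))
            for b in (MATERNAL, PATERNAL, UNCLASSIFIED)
        ]
        return pd.DataFrame(rows, columns=["bin", "n_reads", "bp"])


def _count_hits(canon: np.ndarray, markers: MarkerSet) -> int:
    if canon.size == 0 or len(markers) == 0:
        return 0
    idx = np.searchsorted(markers.codes, canon)
    idx[idx == markers.codes.size] = 0
    return int((markers.codes[idx] == canon).sum())


def classify_read(
    read: io.FastqRead | str,
    maternal: MarkerSet,
    paternal: MarkerSet,
    normalize: bool = False,
) -> ReadBinCall:
    """Assign one read to a haplotype bin by marker window counts.

    Hit counting counts windows, not distinct markers: a marker occurring
    twice in the read contributes 2.  With ``normalize`` the comparison is
    on hits / marker-set size (the convention of earlier trio-binning
    classifiers); the decision still requires a strict winner, so equal
    (normalized) counts and the zero-zero case stay unclassified.  Reads
    shorter than k are unclassified with zero hits.
    """
    if maternal.k != paternal.k:
        raise ValueError(f"marker sets disagree on k: {maternal.k} vs {paternal.k}")
    if isinstance(read, str):
        read = io.FastqRead("read", read, "")
    k = maternal.k
    codes = _seq.encode(read.seq)
    canon, valid = _seq.canonical_codes(codes, k)
    canon = canon[valid]
    mat_hits = _count_hits(canon, maternal)
    pat_hits = _count_hits(canon, paternal)
    if normalize and len(maternal) and len(paternal):
        mat_score = mat_hits / len(maternal)
        pat_score = pat_hits / len(paternal)
    else:
        mat_score, pat_score = float(mat_hits), float(pat_hits)
    if mat_hits == 0 and pat_hits == 0:
        bin_ = UNCLASSIFIED
    elif mat_score > pat_score:
        bin_ = MATERNAL
    elif pat_score > mat_score:
        bin_ = PATERNAL
    else:
        bin_ = UNCLASSIFIED
    return ReadBinCall(read.id, len(read.seq), mat_hits, pat_hits, bin_)


def bin_reads(
    reads: Iterable[io.FastqRead],
    maternal: MarkerSet,
    paternal: MarkerSet,
    normalize: bool = False,
    genome_size: int | None = None,
) -> tuple[dict[str, list[io.FastqRead]], list[ReadBinCall], BinningReport]:
    """Partition a read stream into maternal / paternal / unclassified bins.

    Every input read lands in exactly one bin; bp is conserved.  Unreadable
    records (empty sequence) are skipped with a logged count.
    """
    bins: dict[str, list[io.FastqRead]] = {
        MATERNAL: [],
        PATERNAL: [],
        UNCLASSIFIED: [],
    }
    calls: list[ReadBinCall] = []
    n_bad = 0
    for read in reads:
        if not read.seq:
            n_bad += 1
            continue
        call = classify_read(read, maternal, paternal, normalize=normalize)
        bins[call.bin].append(read)
        calls.append(call)
    if n_bad:
        io.log("bin-reads", f"skipped {n_bad} unreadable record(s)")
    report = summarize_binning(calls, genome_size=genome_size)
    return bins, calls, report


def summarize_binning(
    calls: Iterable[ReadBinCall], genome_size: int | None = None
) -> BinningReport:
    n_reads = {MATERNAL: 0, PATERNAL: 0, UNCLASSIFIED: 0}
    bp = {MATERNAL: 0, PATERNAL: 0, UNCLASSIFIED: 0}
    marker_bp = 0
    for c in calls:
        n_reads[c.bin] += 1
        bp[c.bin] += c.read_length
        if c.maternal_hits or c.paternal_hits:
            marker_bp += c.read_length
    total = sum(bp.values())
    classified = bp[MATERNAL] + bp[PATERNAL]
    coverage = None
    if genome_size:
        coverage = {
            MATERNAL: bp[MATERNAL] / genome_size,
            PATERNAL: bp[PATERNAL] / genome_size,
        }
    return BinningReport(
        n_reads=n_reads,
        bp=bp,
        fraction_of_total_length_classified=(classified / total) if total else 0.0,
        fraction_of_total_length_with_marker=(marker_bp / total) if total else 0.0,
        coverage_per_haplotype=coverage,
    )


def evaluate_binning(calls: Iterable[ReadBinCall], truth: pd.DataFrame) -> dict:
    """Precision/recall per haplotype and misassignment among classified reads.

    ``truth`` is the read truth table (read_id, haplotype).  Missing truth
    for any call is an error.  When no read of a haplotype is classified,
    its precision is undefined (NaN) and flagged.
    """
    hap_of = dict(zip(truth["read_id"], truth["haplotype"]))
    counts = {h: {"tp": 0, "fp": 0, "fn": 0} for h in (MATERNAL, PATERNAL)}
    n_classified = 0
    n_wrong = 0
    for c in calls:
        if c.read_id not in hap_of:
            raise KeyError(f"truth table missing read {c.read_id}")
        true_hap = hap_of[c.read_id]
        if c.bin == UNCLASSIFIED:
            counts[true_hap]["fn"] += 1
            continue
        n_classified += 1
        if c.bin == true_hap:
            counts[true_hap]["tp"] += 1
        else:
            counts[c.bin]["fp"] += 1
            counts[true_hap]["fn"] += 1
            n_wrong += 1
    out: dict = {
        "n_classified": n_classified,
        "misassignment_rate": (n_wrong / n_classified) if n_classified else float("nan"),
        "all_unclassified": n_classified == 0,
    }
    for hap, c in counts.items():
        called = c["tp"] + c["fp"]
        total = c["tp"] + c["fn"]
        out[hap] = {
            "precision": (c["tp"] / called) if called else float("nan"),
            "precision_defined": called > 0,
            "recall": (c["tp"] / total) if total else float("nan"),
        }
    return out
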