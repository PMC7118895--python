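"""Parent-unique marker k-mers for trio binning.

Counts canonical k-mers in each parent's reads, takes the set difference,
and keeps k-mers whose count in their own parent falls inside a window
(at least 4 for the maternal line, at least 6 for the paternal line, below
100 by default).  K-mers passing these filters are diagnostic of haplotype
of origin in the offspring's reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from . import _seq

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"


@dataclass
class MarkerConfig:
    """Thresholds for marker construction.

    k defaults to 21; odd k in [11, 31] is recommended (even k admits
    palindromic k-mers whose canonical form equals their reverse
    complement — allowed, but warned).  Count window is half-open:
    ``min_count <= count < max_count_exclusive``.
    """

    k: int = 21
    min_count_maternal: int = 4
    min_count_paternal: int = 6
    max_count_exclusive: int = 100

    def __post_init__(self) -> None:
        if not (11 <= self.k <= 31):
            raise ValueError(f"k must be in [11, 31], got {self.k}")
        if self.k % 2 == 0:
            warnings.warn(
                f"even k={self.k} admits palindromic k-mers; odd k recommended",
                stacklevel=2,
            )
        for name, lo in (
            ("min_count_maternal", self.min_count_maternal),
            ("min_count_paternal", self.min_count_paternal),
        ):
            if not (0 < lo < self.max_count_exclusive):
                raise ValueError(
                    f"{name}={lo} must satisfy 0 < min < max_count_exclusive="
                    f"{self.max_count_exclusive}"
                )


@dataclass
class KmerCountTable:
    """Canonical k-mer counts as parallel sorted code/count arrays.

    ``codes`` are packed 2-bit canonical k-mer codes (see triobin._seq),
    sorted ascending; ``counts`` are the matching occurrence counts.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    source_label: str = ""

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def get(self, kmer: str) -> int:
        """Count of a k-mer string (canonicalized first); 0 if absent."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        code = np.uint64(_seq.kmer_to_code(_seq.canonical_kmer(kmer)))
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def as_dict(self) -> dict[str, int]:
        """Materialize as {k-mer string: count} (small tables only)."""
        return {
            _seq.code_to_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def items(self) -> Iterator[tuple[str, int]]:
        for c, n in zip(self.codes, self.counts):
            yield _seq.code_to_kmer(int(c), self.k), int(n)


@dataclass
class MarkerSet:
    """Parent-unique k-mers for one haplotype, with their own-parent counts."""

    k: int
    haplotype: str
    codes: np.ndarray
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        code = np.uint64(_seq.kmer_to_code(_seq.canonical_kmer(kmer)))
        i = np.searchsorted(self.codes, code)
        return bool(i < self.codes.size and self.codes[i] == code)

    def to_tsv(self, path) -> None:
        """Serialize as sorted two-column TSV with a header line recording k."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\thaplotype={self.haplotype}\tn={len(self)}\n")
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{_seq.code_to_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def from_tsv(cls, path) -> "MarkerSet":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError(f"{path}: missing marker TSV header")
            fields = dict(f.split("=", 1) for f in header[1:].split("\t"))
            k = int(fields["k"])
            codes, counts = [], []
            for line in fh:
                kmer, n = line.split()
                codes.append(_seq.kmer_to_code(kmer))
                counts.append(int(n))
        order = np.argsort(np.asarray(codes, dtype=np.uint64))
        return cls(
            k=k,
            haplotype=fields.get("haplotype", "?"),
            codes=np.asarray(codes, dtype=np.uint64)[order],
            counts=np.asarray(counts, dtype=np.int64)[order],
        )


def count_kmers(
    sequences: Iterable[str], k: int, source_label: str = ""
) -> KmerCountTable:
    """Count canonical k-mers over a stream of sequences.

    Windows containing any non-ACGT base (N included) are skipped entirely.
    Sequences shorter than k contribute nothing; this is not an error.
    Counting is order-independent by construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chunks: list[np.ndarray] = []
    merged: tuple[np.ndarray, np.ndarray] | None = None
    pending = 0
    # join reads on an N separator so one vectorized pass covers many reads;
    # the N invalidates every window spanning two reads
    batch: list[str] = []
    batch_bp = 0

    def _flush_batch() -> None:
        nonlocal pending
        if not batch:
            return
        joined = "N".join(batch)
        enc = _seq.encode(joined)
        if (enc == 4).any() and set(joined.upper()) - set("ACGTN"):
            bad = sorted(set(joined.upper()) - set("ACGTN"))
            raise ValueError(f"non-IUPAC characters in sequence: {bad}")
        canon, valid = _seq.canonical_codes(enc, k)
        if canon.size:
            chunks.append(canon[valid])
            pending += chunks[-1].size

    for seq in sequences:
        batch.append(seq)
        batch_bp += len(seq)
        if batch_bp >= 4_000_000:
            _flush_batch()
            batch, batch_bp = [], 0
        # bound memory: fold accumulated windows into the running table
        if pending > 32_000_000:
            merged = _fold(merged, chunks)
            chunks, pending = [], 0
    _flush_batch()
    merged = _fold(merged, chunks)
    codes, counts = merged
    return KmerCountTable(k=k, codes=codes, counts=counts, source_label=source_label)


def _fold(
    merged: tuple[np.ndarray, np.ndarray] | None, chunks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    arrays = [c for c in chunks if c.size]
    if not arrays:
        if merged is None:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
        return merged
    codes, counts = np.unique(np.concatenate(arrays), return_counts=True)
    counts = counts.astype(np.int64)
    if merged is not None and merged[0].size:
        codes = np.concatenate([merged[0], codes])
        counts = np.concatenate([merged[1], counts])
        codes, inverse = np.unique(codes, return_inverse=True)
        counts = np.bincount(inverse, weights=counts).astype(np.int64)
    return codes, counts


def build_marker_sets(
    maternal_counts: KmerCountTable,
    paternal_counts: KmerCountTable,
    config: MarkerConfig | None = None,
) -> tuple[MarkerSet, MarkerSet]:
    """Set-difference the parental count tables and apply count windows.

    Maternal markers are canonical k-mers present in the maternal table,
    absent from the paternal table, with maternal count in
    [min_count_maternal, max_count_exclusive); symmetric for paternal with
    its own minimum.  The returned sets are disjoint by construction.
    """
    config = config or MarkerConfig()
    if maternal_counts.k != paternal_counts.k:
        raise ValueError(
            f"k mismatch: maternal k={maternal_counts.k}, paternal k={paternal_counts.k}"
        )
    if maternal_counts.k != config.k:
        raise ValueError(
            f"count tables built with k={maternal_counts.k} but config.k={config.k}"
        )

    def _difference(own: KmerCountTable, other: KmerCountTable, lo: int) -> MarkerSet:
        unique = ~np.isin(own.codes, other.codes, assume_unique=True)
        keep = unique & (own.counts >= lo) & (own.counts < config.max_count_exclusive)
        return MarkerSet(
            k=config.k,
            haplotype="",
            codes=own.codes[keep],
            counts=own.counts[keep],
        )

    mat = _difference(maternal_counts, paternal_counts, config.min_count_maternal)
    mat.haplotype = MATERNAL
    pat = _difference(paternal_counts, maternal_counts, config.min_count_paternal)
    pat.haplotype = PATERNAL
    return mat, pat


def marker_summary(maternal: MarkerSet, paternal: MarkerSet) -> dict:
    """Marker counts per haplotype, count histograms, and the size ratio."""

    def _hist(ms: MarkerSet) -> dict[int, int]:
        if not len(ms):
            return {}
        values, freqs = np.unique(ms.counts, return_counts=True)
        return {int(v): int(f) for v, f in zip(values, freqs)}

    n_mat, n_pat = len(maternal), len(paternal)
    return {
        "k": maternal.k,
        "n_maternal": n_mat,
        "n_paternal": n_pat,
        "ratio_maternal_to_paternal": (n_mat / n_pat) if n_pat else float("nan"),
        "count_histogram_maternal": _hist(maternal),
        "count_histogram_paternal": _hist(paternal),
    }
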