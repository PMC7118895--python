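"""Low-level sequence utilities: 2-bit encoding and vectorized canonical k-mer codes.

Bases are encoded A=0, C=1, G=2, T=3; anything else (including N) maps to 4
and invalidates every k-mer window that covers it.  A k-mer is packed into a
uint64 as a base-4 number, most significant digit first, so lexicographic
order on strings equals numeric order on codes; this is what makes the
canonical form (min of forward and reverse-complement code) cheap.  k <= 31
fits in 62 bits.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGT"))

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N kept)."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for code arrays without 4s."""
    return "".join(_DECODE[codes])


def kmer_to_code(kmer: str) -> int:
    """Pack a k-mer string into its integer code."""
    codes = encode(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT base: {kmer!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def code_to_kmer(code: int, k: int) -> str:
    """Unpack an integer k-mer code back to its string."""
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes for every window of an encoded sequence.

    Returns ``(fwd, valid)`` where ``fwd[i]`` is the packed code of window
    ``[i, i+k)`` and ``valid[i]`` is False when the window covers a non-ACGT
    base.  Empty arrays when the sequence is shorter than k.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    safe = np.where(codes > 3, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= safe[j : j + n] << np.uint64(2 * (k - 1 - j))
    bad = (codes > 3).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return fwd, valid


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of strand pair) k-mer codes for every valid window.

    Same return convention as :func:`kmer_codes`.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    fwd, valid = kmer_codes(codes, k)
    comp = np.where(codes > 3, 0, 3 - codes).astype(np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    # reverse complement read right-to-left: base at window offset j lands at
    # significance j
    for j in range(k):
        rev |= comp[j : j + n] << np.uint64(2 * j)
    return np.minimum(fwd, rev), valid


def canonical_kmer(kmer: str) -> str:
    """Canonical form of one k-mer string (lexicographic min with revcomp)."""
    rc = revcomp(kmer.upper())
    return min(kmer.upper(), rc)
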