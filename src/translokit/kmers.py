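"""Vectorized 2-bit k-mer encoding shared by the anchor aligner and the
primer-uniqueness screen.

A k-mer of length k <= 31 is packed into an int64 (2 bits per base, A=0,
C=1, G=2, T=3, first base most significant).  Canonical form is the
lexicographic minimum of a k-mer and its reverse complement; odd k avoids
self-reverse-complement palindromes.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

MAX_K = 31


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGT string to uint8 codes 0..3."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        raise ValueError("sequence contains non-ACGT symbols")
    return arr


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (forward codes, reverse-complement codes) for every k-mer.

    Entry i corresponds to the window starting at 0-based offset i.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}")
    codes = encode_sequence(seq).astype(np.int64)
    if codes.size < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    w_fwd = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ w_fwd
    # reverse complement of window = complemented bases read right-to-left
    w_rev = 4 ** np.arange(k, dtype=np.int64)
    rc = (3 - win) @ w_rev
    return fwd, rc


def canonical_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes and a flag (True where forward is canonical)."""
    fwd, rc = kmer_codes(seq, k)
    fwd_is_canonical = fwd <= rc
    return np.where(fwd_is_canonical, fwd, rc), fwd_is_canonical


def encode_kmer(kmer: str) -> int:
    arr = encode_sequence(kmer).astype(np.int64)
    w = 4 ** np.arange(len(arr) - 1, -1, -1, dtype=np.int64)
    return int(arr @ w)


def canonical_kmer_code(kmer: str) -> int:
    arr = encode_sequence(kmer).astype(np.int64)
    k = len(arr)
    fwd = int(arr @ (4 ** np.arange(k - 1, -1, -1, dtype=np.int64)))
    rc = int((3 - arr) @ (4 ** np.arange(k, dtype=np.int64)))
    return min(fwd, rc)
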