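"""Vectorized contiguous k-mer counting shared by the I/O and spectrum layers.

Bases are coded A=0, C=1, G=2, T=3; N (or any other ambiguity code already
rejected upstream) codes to -1 and invalidates every window it touches.
A contiguous k-mer maps to its base-4 integer with the leftmost base as the
most significant digit, so lexicographic word order equals numeric order.
"""
from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """Map a residue string to int8 codes (N -> -1)."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def decode_kmer(index: int, k: int) -> str:
    """Inverse of the base-4 encoding: integer index -> k-mer string."""
    chars = []
    for p in range(k):
        chars.append(ALPHABET[(index >> (2 * (k - 1 - p))) & 3])
    return "".join(chars)


def kmer_index(word: str) -> int:
    idx = 0
    for ch in word:
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"not an unambiguous DNA word: {word!r}")
        idx = (idx << 2) | int(code)
    return idx


def kmer_counts(residues: str, k: int) -> np.ndarray:
    """Overlapping contiguous k-mer counts; windows containing N contribute 0.

    Returns an int64 array of length 4**k (all zeros when len(residues) < k).
    """
    counts = np.zeros(4**k, dtype=np.int64)
    if len(residues) < k:
        return counts
    codes = encode(residues)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid].astype(np.int64) @ powers
    np.add.at(counts, idx, 1)
    return counts


def n_windows(length: int, k: int) -> int:
    """Number of sliding windows |chi| - k + 1 (0 when the sequence is short)."""
    return max(length - k + 1, 0)
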