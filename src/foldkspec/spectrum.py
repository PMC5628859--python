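"""The folded k-spectrum feature map.

A *gap mask* is a binary dependency pattern over k positions (1 = dependent
nucleotide, 0 = gap).  Written with position 1 as the most significant bit,
mask decimals are odd — the last position is always dependent, since a
trailing gap merely duplicates a shorter mask at a shifted offset.  There are
2^(k-1) masks, and the model with all bits set is the ordinary contiguous
k-mer model.

A sequence is mapped once to its contiguous k-spectrum (counts of all 4^k
k-mers), normalized to relative frequencies against a background model, and
then *folded*: the value of a gapped feature, e.g. ANA, is the sum of the
normalized values of every contiguous k-mer agreeing with it at the dependent
positions (phi_ANA = phi_AAA + phi_ACA + phi_AGA + phi_ATA).  Folding is a
single sparse matrix product, so the full feature space of dimension
4 * 5^(k-1) costs little more than plain k-mer counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import scipy.sparse as sp

from ._kmers import ALPHABET, decode_kmer, kmer_counts, n_windows
from .seqio import BackgroundModel, Sequence

GAP = "N"

RAW_COUNT = "raw_count"
RAW_FREQUENCY = "raw_frequency"
NORMALIZED = "normalized"

CONTIGUOUS = "contiguous"
FULL = "full"

MAX_K = 12


class NormalizationError(ValueError):
    """Raised when a k-mer has zero background frequency but a nonzero count."""


@dataclass(frozen=True)
class GapMask:
    """One gapped dependency model: k positions, dependent where the bit is 1."""

    k: int
    decimal: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        if not 1 <= self.decimal < 2**self.k:
            raise ValueError(f"mask decimal {self.decimal} out of range for k={self.k}")
        if self.decimal % 2 == 0:
            raise ValueError(
                f"mask decimal {self.decimal} is even: trailing gaps are excluded"
            )

    @property
    def bits(self) -> tuple[bool, ...]:
        """Dependency bits, position 1 (leftmost) first."""
        return tuple(bool((self.decimal >> (self.k - 1 - p)) & 1) for p in range(self.k))

    @property
    def model_index(self) -> int:
        """m in 1..2^(k-1), with decimal = 2m - 1."""
        return (self.decimal + 1) // 2

    @property
    def popcount(self) -> int:
        return bin(self.decimal).count("1")

    @property
    def dependent_positions(self) -> tuple[int, ...]:
        """0-based positions carrying a nucleotide (non-gap)."""
        return tuple(p for p, bit in enumerate(self.bits) if bit)

    @property
    def n_features(self) -> int:
        return 4**self.popcount

    def pattern(self, word: str) -> str:
        """Place a dependent-position word into the mask, N at gaps."""
        if len(word) != self.popcount:
            raise ValueError(
                f"word {word!r} has {len(word)} letters; mask needs {self.popcount}"
            )
        out = [GAP] * self.k
        for ch, pos in zip(word, self.dependent_positions):
            out[pos] = ch
        return "".join(out)

    def __str__(self) -> str:  # e.g. 101 for k=3, decimal 5
        return "".join("1" if b else "0" for b in self.bits)


def enumerate_models(k: int) -> list[GapMask]:
    """All 2^(k-1) gap masks for word length k, in ascending decimal order."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    return [GapMask(k, d) for d in range(1, 2**k, 2)]


@dataclass(frozen=True)
class FeatureSpace:
    """The indexed union of all gapped k-mer features across all models.

    Models are ordered by ascending mask decimal; within a model, features
    are ordered lexicographically by their dependent-position word.  The
    global (0-based) index of a feature is its model offset plus the base-4
    encoding of its word.  Total dimension N = 4 * 5^(k-1).
    """

    k: int
    masks: tuple[GapMask, ...]
    offsets: np.ndarray  # length n_models + 1, cumulative feature counts

    @property
    def n_features(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_models(self) -> int:
        return len(self.masks)

    @property
    def contiguous_slice(self) -> slice:
        """Global index range of the contiguous (all-ones mask) model block."""
        return slice(int(self.offsets[-2]), int(self.offsets[-1]))

    def model_of(self, index: int) -> GapMask:
        """The gap mask owning global feature index `index`."""
        if not 0 <= index < self.n_features:
            raise IndexError(f"feature index {index} out of range 0..{self.n_features-1}")
        j = int(np.searchsorted(self.offsets, index, side="right")) - 1
        return self.masks[j]

    def feature_name(self, index: int) -> str:
        """Render a global index as its gapped pattern string, e.g. 'ANT'."""
        mask = self.model_of(index)
        j = self.masks.index(mask)
        word = decode_kmer(index - int(self.offsets[j]), mask.popcount)
        return mask.pattern(word)

    def feature_index(self, pattern: str) -> int:
        """Inverse of feature_name: gapped pattern string -> global index."""
        if len(pattern) != self.k:
            raise ValueError(f"pattern {pattern!r} is not length k={self.k}")
        if pattern[-1] == GAP:
            raise ValueError(f"pattern {pattern!r} has a trailing gap")
        decimal = int("".join("0" if ch == GAP else "1" for ch in pattern), 2)
        mask = GapMask(self.k, decimal)
        j = mask.model_index - 1
        from ._kmers import kmer_index

        word = "".join(ch for ch in pattern if ch != GAP)
        return int(self.offsets[j]) + kmer_index(word)

    def feature_names(self) -> list[str]:
        return [self.feature_name(n) for n in range(self.n_features)]

    def fold_matrix(self) -> sp.csr_matrix:
        """Sparse (4^k x N) matrix F with F[c, n] = 1 iff contiguous k-mer c
        agrees with gapped feature n at its dependent positions."""
        return _fold_matrix(self.k)


@lru_cache(maxsize=None)
def feature_space(k: int) -> FeatureSpace:
    """Build the full gapped feature space for word length k."""
    masks = tuple(enumerate_models(k))
    sizes = np.array([m.n_features for m in masks], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return FeatureSpace(k=k, masks=masks, offsets=offsets)


@lru_cache(maxsize=None)
def _fold_matrix(k: int) -> sp.csr_matrix:
    space = feature_space(k)
    n_contig = 4**k
    # digit matrix: D[c, p] = base at position p of contiguous k-mer c
    c = np.arange(n_contig, dtype=np.int64)
    digits = np.stack([(c >> (2 * (k - 1 - p))) & 3 for p in range(k)], axis=1)
    rows, cols = [], []
    for j, mask in enumerate(space.masks):
        dep = np.array(mask.dependent_positions, dtype=np.int64)
        powers = 4 ** np.arange(len(dep) - 1, -1, -1, dtype=np.int64)
        local = digits[:, dep] @ powers
        rows.append(c)
        cols.append(int(space.offsets[j]) + local)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(len(rows), dtype=np.float64)
    return sp.csr_matrix((data, (rows, cols)), shape=(n_contig, space.n_features))


@dataclass
class SpectrumVector:
    """A sequence's feature values at one pipeline stage.

    scope 'contiguous' holds the 4^k contiguous k-mer coordinates only;
    scope 'full' holds all N folded coordinates.  `active_index` (global,
    0-based) is set when the vector has been restricted to a feature subset.
    """

    sequence_id: str
    k: int
    stage: str
    scope: str
    values: np.ndarray
    active_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.active_index is not None:
            self.active_index = np.asarray(self.active_index, dtype=np.int64)
            if len(self.active_index) != len(self.values):
                raise ValueError("active_index and values lengths differ")


def count_contiguous(seq: Sequence, k: int) -> SpectrumVector:
    """Overlapping contiguous k-mer counts (windows containing N dropped)."""
    if len(seq.residues) < k:
        raise ValueError(
            f"sequence {seq.id!r} (length {len(seq.residues)}) is shorter than k={k}"
        )
    return SpectrumVector(
        sequence_id=seq.id,
        k=k,
        stage=RAW_COUNT,
        scope=CONTIGUOUS,
        values=kmer_counts(seq.residues, k).astype(np.float64),
    )


def normalize(
    counts: SpectrumVector, seq_length: int, bg: BackgroundModel
) -> SpectrumVector:
    """Relative-frequency normalization of a contiguous count vector.

    phi_alpha = [count_alpha / (L - k + 1)] / [background frequency of alpha],
    cancelling sequence-length and background-composition effects.
    """
    if counts.stage != RAW_COUNT or counts.scope != CONTIGUOUS:
        raise ValueError("normalize expects a contiguous raw-count vector")
    if bg.k != counts.k:
        raise ValueError(f"background k={bg.k} does not match vector k={counts.k}")
    freq = counts.values / n_windows(seq_length, counts.k)
    bg_freq = bg.frequencies()
    zero = (bg_freq == 0) & (counts.values > 0)
    if zero.any():
        alpha = decode_kmer(int(np.flatnonzero(zero)[0]), counts.k)
        raise NormalizationError(
            f"k-mer {alpha} observed in {counts.sequence_id!r} has zero background "
            "frequency; use a positive pseudocount"
        )
    values = np.divide(freq, bg_freq, out=np.zeros_like(freq), where=bg_freq > 0)
    return SpectrumVector(
        sequence_id=counts.sequence_id,
        k=counts.k,
        stage=NORMALIZED,
        scope=CONTIGUOUS,
        values=values,
    )


def fold(contiguous: SpectrumVector, space: FeatureSpace) -> SpectrumVector:
    """Fold a contiguous-spectrum vector into the full gapped feature space.

    Every gapped coordinate is the (unweighted) sum of the contiguous
    coordinates compatible with it; the contiguous block passes through
    unchanged.
    """
    if contiguous.scope != CONTIGUOUS:
        raise ValueError("fold expects a contiguous-scope vector")
    if contiguous.k != space.k:
        raise ValueError(f"vector k={contiguous.k} does not match space k={space.k}")
    if len(contiguous.values) != 4**space.k:
        raise ValueError("contiguous vector dimension mismatch with feature space")
    full = contiguous.values @ space.fold_matrix()
    return SpectrumVector(
        sequence_id=contiguous.sequence_id,
        k=contiguous.k,
        stage=contiguous.stage,
        scope=FULL,
        values=np.asarray(full).ravel(),
    )


def featurize(seq: Sequence, space: FeatureSpace, bg: BackgroundModel) -> SpectrumVector:
    """count -> normalize -> fold: the full folded k-spectrum map Psi_k."""
    counts = count_contiguous(seq, space.k)
    return fold(normalize(counts, len(seq.residues), bg), space)


def featurize_matrix(
    sequences: TypingSequence[Sequence], space: FeatureSpace, bg: BackgroundModel
) -> np.ndarray:
    """Stack featurize() over a sequence list into an (n, N) matrix."""
    k = space.k
    fold_m = space.fold_matrix()
    rows = []
    for seq in sequences:
        counts = count_contiguous(seq, k)
        rows.append(normalize(counts, len(seq.residues), bg).values)
    contiguous = np.vstack(rows)
    return np.asarray(contiguous @ fold_m)


def restrict(v: SpectrumVector, index_set: Iterable[int]) -> SpectrumVector:
    """Constrain a full-scope vector to a feature index subset (Psi_k^h)."""
    if v.scope != FULL:
        raise ValueError("restrict expects a full-scope vector")
    idx = np.array(sorted(set(int(i) for i in index_set)), dtype=np.int64)
    n_total = 4 * 5 ** (v.k - 1)
    if len(idx) and (idx[0] < 0 or idx[-1] >= n_total):
        raise IndexError(f"feature index out of range 0..{n_total - 1}")
    if v.active_index is None:
        values = v.values[idx] if len(idx) else np.empty(0)
    else:
        pos = {int(g): i for i, g in enumerate(v.active_index)}
        missing = [i for i in idx if int(i) not in pos]
        if missing:
            raise IndexError(
                f"index {missing[0]} not in the vector's active index set"
            )
        values = v.values[[pos[int(i)] for i in idx]]
    return SpectrumVector(
        sequence_id=v.sequence_id,
        k=v.k,
        stage=v.stage,
        scope=FULL,
        values=values,
        active_index=idx,
    )


def count_gapped_direct(residues: str, pattern: str) -> int:
    """Directly count sliding windows matching a gapped pattern.

    N in the pattern is a wildcard; windows containing N in the *sequence*
    never match (mirroring the count-then-fold path, which drops them).
    Used for direct pattern queries and as an alternative to folding.
    """
    k = len(pattern)
    count = 0
    for start in range(len(residues) - k + 1):
        window = residues[start : start + k]
        if "N" in window:
            continue
        if all(p == GAP or p == w for p, w in zip(pattern, window)):
            count += 1
    return count
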