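"""Sequence input/output and background models.

This layer owns the data the classifier never sees directly: FASTA records,
their composition-preserving scrambles (the negative / null sets), and the
genomic background k-mer frequencies used to normalize spectra.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._kmers import ALPHABET, decode_kmer, kmer_counts, n_windows

VALID_RESIDUES = frozenset("ACGTN")

ORIGINAL = "original"
SCRAMBLED = "scrambled"


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


class ValidationError(ValueError):
    """Raised when a sequence violates the residue alphabet or linkage rules."""


@dataclass(frozen=True)
class Sequence:
    """A DNA sequence with an optional class label and scramble provenance.

    `label` is +1 for putative regulatory (positive) sequences and -1 for
    background/negative sequences. A scrambled sequence records the id of the
    original it permutes in `parent_id`.
    """

    id: str
    residues: str
    label: int | None = None
    origin: str = ORIGINAL
    parent_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            pos = next(
                i for i, ch in enumerate(self.residues) if ch not in VALID_RESIDUES
            )
            raise ValidationError(
                f"sequence {self.id!r}: illegal residue {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )
        if self.origin not in (ORIGINAL, SCRAMBLED):
            raise ValidationError(f"sequence {self.id!r}: unknown origin {self.origin!r}")
        if (self.parent_id is not None) != (self.origin == SCRAMBLED):
            raise ValidationError(
                f"sequence {self.id!r}: parent_id must be set iff origin is scrambled"
            )
        if self.label not in (None, 1, -1):
            raise ValidationError(f"sequence {self.id!r}: label must be +1/-1/None")

    def __len__(self) -> int:
        return len(self.residues)

    def with_label(self, label: int | None) -> "Sequence":
        return replace(self, label=label)


def read_fasta(path: str | Path, label: int | None = None) -> list[Sequence]:
    """Read a FASTA file into validated Sequence records.

    Record ids are the header up to the first whitespace; residues are
    uppercased.  An illegal residue raises ValidationError naming the record
    and position; text before the first header raises FastaError naming the
    line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            Sequence(id=rec.id, residues=str(rec.seq), label=label)
        )
    return records


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 80) -> None:
    """Write sequences to FASTA, wrapped at `width` columns."""
    with open(path, "w") as handle:
        for seq in sequences:
            handle.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), width):
                handle.write(seq.residues[start : start + width] + "\n")


def _copy_rng(seed: int, parent_id: str, copy_index: int) -> np.random.Generator:
    # Per-copy seed stream (seed, parent id, copy index) so each scramble is
    # reproducible independently of how many copies are requested.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(parent_id.encode()), copy_index])
    )


def scramble(
    seq: Sequence, n_copies: int, seed: int, label: int | None = -1
) -> list[Sequence]:
    """Uniform random permutations of a sequence's residues.

    Each copy conserves the parent's residue multiset exactly and records the
    parent id; copies are deterministic given (seed, parent id, copy index).
    """
    if n_copies < 1:
        raise ValueError(f"n_copies must be >= 1, got {n_copies}")
    residues = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    copies = []
    for j in range(n_copies):
        rng = _copy_rng(seed, seq.id, j)
        permuted = rng.permutation(residues).tobytes().decode("ascii")
        copies.append(
            Sequence(
                id=f"{seq.id}_scr{j}",
                residues=permuted,
                label=label,
                origin=SCRAMBLED,
                parent_id=seq.id,
            )
        )
    return copies


@dataclass
class BackgroundModel:
    """Contiguous k-mer occurrence counts of a background ('genome') set.

    The background frequency of k-mer alpha is
    (counts[alpha] + pseudocount) / (total_windows + 4^k * pseudocount);
    a positive pseudocount keeps every frequency strictly positive on small
    backgrounds.
    """

    k: int
    counts: np.ndarray  # int64, length 4**k
    total_windows: int
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have 4^k = {4**self.k} entries, got {self.counts.shape}"
            )
        if self.total_windows < 1:
            raise ValueError("background must contain at least one k-mer window")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    def frequencies(self) -> np.ndarray:
        """Background frequency for every contiguous k-mer (length 4**k)."""
        denom = self.total_windows + (4**self.k) * self.pseudocount
        return (self.counts + self.pseudocount) / denom

    @classmethod
    def uniform(cls, k: int) -> "BackgroundModel":
        """Flat background: every contiguous k-mer at frequency 4^-k."""
        return cls(k=k, counts=np.ones(4**k, dtype=np.int64),
                   total_windows=4**k, pseudocount=0.0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(
                f"#k={self.k}\ttotal_windows={self.total_windows}"
                f"\tpseudocount={self.pseudocount}\n"
            )
            for idx in range(4**self.k):
                handle.write(f"{decode_kmer(idx, self.k)}\t{self.counts[idx]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackgroundModel":
        with open(path) as handle:
            header = handle.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing background header line")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
            )
            k = int(meta["k"])
            counts = np.zeros(4**k, dtype=np.int64)
            from ._kmers import kmer_index

            for line in handle:
                word, count = line.split("\t")
                counts[kmer_index(word)] = int(count)
        return cls(
            k=k,
            counts=counts,
            total_windows=int(meta["total_windows"]),
            pseudocount=float(meta["pseudocount"]),
        )


def build_background(
    sequences: TypingSequence[Sequence], k: int, pseudocount: float = 1.0
) -> BackgroundModel:
    """Sum sliding-window k-mer counts over a sequence set.

    Windows containing N contribute nothing to the counts, but the window
    total keeps the printed |chi| - k + 1 denominator.  Sequences shorter
    than k contribute no windows; an error is raised only when no window
    exists at all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    total = 0
    for seq in sequences:
        counts += kmer_counts(seq.residues, k)
        total += n_windows(len(seq.residues), k)
    if total < 1:
        raise ValueError(f"no sequence of length >= k={k} in the background set")
    return BackgroundModel(k=k, counts=counts, total_windows=total,
                           pseudocount=pseudocount)
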