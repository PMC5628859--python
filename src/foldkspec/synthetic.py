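"""Synthetic datasets with known ground truth.

Generates i.i.d. background DNA, plants copies of a (possibly gapped)
consensus motif at non-overlapping random positions, and pairs each positive
with composition-preserving scrambled negatives — the same construction the
classifier is meant for, but with the planted motif and its gap structure
known exactly, so recovery can be scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np

from . import seqio
from .seqio import Sequence

_BASES = "ACGT"
UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PlantSpec:
    """How motif instances are planted.

    `consensus` is a word over {A,C,G,T,N}; N positions are left as the
    background residue (unconstrained), the rest are written, each mutated
    to one of the other three bases with probability `mutation_rate`.
    """

    consensus: str
    plants_per_sequence: int = 3
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.consensus) < 1:
            raise ValueError("consensus must be non-empty")
        if set(self.consensus) - set(_BASES + "N"):
            raise ValueError(f"bad consensus {self.consensus!r}")
        if self.consensus.count("N") == len(self.consensus):
            raise ValueError("consensus needs at least one dependent position")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.plants_per_sequence < 0:
            raise ValueError("plants_per_sequence must be >= 0")


@dataclass
class PlantRecord:
    sequence_id: str
    offset: int  # 1-based
    word: str  # the realized k-length window after planting


@dataclass
class Dataset:
    """A labeled synthetic dataset plus its ground-truth plant log."""

    sequences: list[Sequence]
    plant_log: list[PlantRecord]
    params: dict

    @property
    def positives(self) -> list[Sequence]:
        return [s for s in self.sequences if s.label == 1]

    @property
    def negatives(self) -> list[Sequence]:
        return [s for s in self.sequences if s.label == -1]


def generate_background(
    n: int,
    length: int,
    composition: TypingSequence[float] = UNIFORM,
    seed: int = 0,
    prefix: str = "pos",
) -> list[Sequence]:
    """i.i.d. background sequences with the given base composition."""
    composition = np.asarray(composition, dtype=np.float64)
    if abs(composition.sum() - 1.0) > 1e-9:
        raise ValueError("composition probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        codes = rng.choice(4, size=length, p=composition)
        residues = "".join(_BASES[c] for c in codes)
        out.append(Sequence(id=f"{prefix}_{i:03d}", residues=residues, label=1))
    return out


def plant_motifs(
    sequences: TypingSequence[Sequence], spec: PlantSpec
) -> tuple[list[Sequence], list[PlantRecord]]:
    """Write non-overlapping motif instances into each sequence.

    Returns the modified sequences and a log of (id, 1-based offset,
    realized window).  Raises if the requested number of non-overlapping
    plants cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    klen = len(spec.consensus)
    out_seqs: list[Sequence] = []
    log: list[PlantRecord] = []
    for seq in sequences:
        if spec.plants_per_sequence == 0:
            out_seqs.append(seq)
            continue
        if len(seq.residues) < klen:
            raise ValueError(f"sequence {seq.id!r} shorter than the consensus")
        starts = _non_overlapping_starts(
            rng, len(seq.residues), klen, spec.plants_per_sequence, seq.id
        )
        residues = list(seq.residues)
        for start in starts:
            for p, ch in enumerate(spec.consensus):
                if ch == "N":
                    continue
                base = ch
                if spec.mutation_rate > 0 and rng.random() < spec.mutation_rate:
                    base = rng.choice([b for b in _BASES if b != ch])
                residues[start + p] = base
            word = "".join(residues[start : start + klen])
            log.append(PlantRecord(seq.id, start + 1, word))
        out_seqs.append(
            Sequence(
                id=seq.id,
                residues="".join(residues),
                label=seq.label,
                origin=seq.origin,
                parent_id=seq.parent_id,
            )
        )
    return out_seqs, log


def _non_overlapping_starts(
    rng: np.random.Generator, length: int, klen: int, n_plants: int, seq_id: str
) -> list[int]:
    # greedy pass over a shuffled start list; finds a maximal packing
    candidates = rng.permutation(length - klen + 1)
    chosen: list[int] = []
    for start in candidates:
        if all(abs(start - s) >= klen for s in chosen):
            chosen.append(int(start))
            if len(chosen) == n_plants:
                return sorted(chosen)
    raise ValueError(
        f"cannot place {n_plants} non-overlapping plants of length {klen} "
        f"in sequence {seq_id!r} (length {length})"
    )


def make_dataset(
    spec: PlantSpec,
    n_pos: int = 60,
    length: int = 600,
    n_scrambles: int = 10,
    seed: int = 0,
    composition: TypingSequence[float] = UNIFORM,
) -> Dataset:
    """Planted positives plus matched scrambled negatives.

    Background and scramble randomness derive from `seed`; plant positions
    and mutations derive from `spec.seed`.
    """
    backgrounds = generate_background(n_pos, length, composition, seed=seed)
    positives, log = plant_motifs(backgrounds, spec)
    sequences: list[Sequence] = list(positives)
    for p in positives:
        sequences.extend(seqio.scramble(p, n_scrambles, seed=seed + 1, label=-1))
    return Dataset(
        sequences=sequences,
        plant_log=log,
        params={
            "n_pos": n_pos,
            "length": length,
            "n_scrambles": n_scrambles,
            "seed": seed,
            "consensus": spec.consensus,
            "plants_per_sequence": spec.plants_per_sequence,
            "mutation_rate": spec.mutation_rate,
            "plant_seed": spec.seed,
        },
    )


def write_plant_log(log: TypingSequence[PlantRecord], path) -> None:
    with open(path, "w") as handle:
        handle.write("sequence_id\toffset\tstrand\tword\n")
        for rec in log:
            handle.write(f"{rec.sequence_id}\t{rec.offset}\t+\t{rec.word}\n")
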