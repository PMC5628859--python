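"""Feature enrichment, motif fragments, and false-discovery elimination.

After SVM training, the enrichment score of feature n in a sequence is
r(n) = w(n) * x(n): the product of the learned weight and the sequence's
feature value.  Features scoring above a cutoff (default 0.005) are the
sequence's top-enriched gapped k-mers; per gap-mask model they assemble into
a *motif fragment* such as (A/T)NT, exportable as a position frequency
matrix for comparison against motif databases.

Because composition alone can enrich features that are no binding sites, a
second SVM trained on scrambled copies of the positives identifies features
that remain enriched on pure background; those are eliminated from each
positive's profile, and the union of surviving features is the
high-confidence feature set the final classifier is constrained to.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd

from . import classifier, seqio
from .classifier import TrainedModel
from .seqio import BackgroundModel, Sequence
from .spectrum import (
    GAP,
    FeatureSpace,
    GapMask,
    SpectrumVector,
    featurize_matrix,
)

DEFAULT_CUTOFF = 0.005
DEFAULT_HIT_P = 1e-3

BY_MODEL = "by_model"
BY_FEATURE = "by_feature"

_BASES = "ACGT"


@dataclass
class EnrichmentProfile:
    """Per-sequence enrichment scores r(n) = w(n) x(n) over an index set."""

    sequence_id: str
    scores: np.ndarray
    index: np.ndarray  # global feature indices aligned with scores
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.index = np.asarray(self.index, dtype=np.int64)
        if self.scores.shape != self.index.shape:
            raise ValueError("scores and index must be aligned")

    @property
    def selected(self) -> np.ndarray:
        """Global indices with score strictly above the cutoff."""
        return self.index[self.scores > self.cutoff]


def enrichment_scores(
    model: TrainedModel,
    x: SpectrumVector,
    cutoff: float = DEFAULT_CUTOFF,
) -> EnrichmentProfile:
    """Elementwise w * x; selection uses strict > cutoff."""
    values = classifier._check_index(model, x)
    if model.active_index is not None:
        index = np.asarray(model.active_index, dtype=np.int64)
    else:
        index = np.arange(len(model.w), dtype=np.int64)
    return EnrichmentProfile(
        sequence_id=x.sequence_id,
        scores=model.w * values,
        index=index,
        cutoff=cutoff,
    )


@dataclass
class MotifFragment:
    """Selected features of one gap-mask model in one sequence.

    `counts` is a (k, 4) matrix of nucleotide counts over member features at
    dependent positions; gap positions are all-zero rows and render as N.
    """

    sequence_id: str
    mask: "GapMask"
    member_patterns: list[str]
    counts: np.ndarray

    @property
    def fragment_id(self) -> str:
        return f"{self.sequence_id}|m{self.mask.decimal}"

    def render(self) -> str:
        """Human-readable consensus like (A/T)NT."""
        out = []
        for p, bit in enumerate(self.mask.bits):
            if not bit:
                out.append(GAP)
                continue
            present = [b for i, b in enumerate(_BASES) if self.counts[p, i] > 0]
            out.append(present[0] if len(present) == 1 else "(" + "/".join(present) + ")")
        return "".join(out)


def parse_rendered(rendered: str) -> list[frozenset[str]]:
    """Parse a rendered fragment back to per-position nucleotide sets.

    Gap positions map to the empty set.
    """
    out: list[frozenset[str]] = []
    i = 0
    while i < len(rendered):
        ch = rendered[i]
        if ch == GAP:
            out.append(frozenset())
            i += 1
        elif ch == "(":
            j = rendered.index(")", i)
            out.append(frozenset(rendered[i + 1 : j].split("/")))
            i = j + 1
        else:
            out.append(frozenset(ch))
            i += 1
    return out


def build_fragments(
    profile: EnrichmentProfile, space: FeatureSpace
) -> list[MotifFragment]:
    """Group a profile's selected features by gap mask into motif fragments."""
    selected = profile.selected
    by_mask: dict[int, list[int]] = {}
    for n in selected:
        mask = space.model_of(int(n))
        by_mask.setdefault(mask.decimal, []).append(int(n))
    fragments = []
    for decimal in sorted(by_mask):
        mask = space.masks[(decimal + 1) // 2 - 1]
        patterns = [space.feature_name(n) for n in by_mask[decimal]]
        counts = np.zeros((space.k, 4), dtype=np.int64)
        for pat in patterns:
            for p, ch in enumerate(pat):
                if ch != GAP:
                    counts[p, _BASES.index(ch)] += 1
        fragments.append(
            MotifFragment(
                sequence_id=profile.sequence_id,
                mask=mask,
                member_patterns=patterns,
                counts=counts,
            )
        )
    return fragments


def export_meme(fragments: TypingSequence[MotifFragment], path: str | Path) -> None:
    """Write fragments as MEME minimal motifs.

    Dependent positions carry counts normalized to probabilities; gap
    positions are emitted as the uniform 0.25 row.
    """
    if not fragments:
        raise ValueError("no fragments to export")
    with open(path, "w") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        handle.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for frag in fragments:
            n_sites = len(frag.member_patterns)
            handle.write(f"MOTIF {frag.fragment_id} {frag.render()}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {frag.mask.k} "
                f"nsites= {n_sites} E= 0\n"
            )
            for p, bit in enumerate(frag.mask.bits):
                if bit:
                    row = frag.counts[p] / frag.counts[p].sum()
                else:
                    row = np.full(4, 0.25)
                handle.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            handle.write("\n")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a motif-comparison hit table TSV (fragment_id, motif_id, p_value)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["fragment_id", "motif_id", "p_value"]
    df["p_value"] = df["p_value"].astype(float)
    return df


@dataclass
class FeatureFilter:
    """The false-feature sets discovered from scrambled-positive training.

    Keys of `false_models_by_parent` / `false_features_by_parent` are the
    original positive ids; `by_copy` records each scrambled copy's enriched
    (false) feature indices.
    """

    by_copy: dict[str, set[int]] = field(default_factory=dict)
    parent_of_copy: dict[str, str] = field(default_factory=dict)
    false_features_by_parent: dict[str, set[int]] = field(default_factory=dict)
    false_models_by_parent: dict[str, set[int]] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "FeatureFilter":
        return cls()

    @property
    def is_empty(self) -> bool:
        return not self.false_models_by_parent


def discover_false_features(
    positives: TypingSequence[Sequence],
    space: FeatureSpace,
    n_scrambles: int = 10,
    n_neg_scrambles: int | None = None,
    C: float = 1.0,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
    bg: BackgroundModel | None = None,
    pseudocount: float = 1.0,
    hits: pd.DataFrame | None = None,
    hit_p_threshold: float = DEFAULT_HIT_P,
) -> FeatureFilter:
    """Train on scrambled positives to find composition-driven enrichments.

    Each positive is replaced by `n_scrambles` scrambled copies, which form a
    'false' positive set; their own scrambles (same multiplicity by default)
    form the negative set.  A fresh SVM with the folded kernel is trained on
    this data, and each copy's features enriched above the cutoff are flagged
    false.  If a motif-database hit table is supplied, a flagged feature is
    retained as false only when its motif fragment has a database hit with
    p-value below `hit_p_threshold` (features without a significant hit are
    deemed insignificant false positives and dropped from the false set).
    """
    if n_neg_scrambles is None:
        n_neg_scrambles = n_scrambles
    false_pos: list[Sequence] = []
    for p in positives:
        false_pos.extend(seqio.scramble(p, n_scrambles, seed=seed, label=1))
    negatives: list[Sequence] = []
    for fp in false_pos:
        negatives.extend(seqio.scramble(fp, n_neg_scrambles, seed=seed + 1, label=-1))
    dataset = false_pos + negatives
    if bg is None:
        bg = seqio.build_background(dataset, space.k, pseudocount=pseudocount)
    X = featurize_matrix(dataset, space, bg)
    y = np.array([s.label for s in dataset], dtype=np.float64)
    model = classifier.train(X, y, C=C, seed=seed)

    filt = FeatureFilter()
    for p in positives:
        filt.false_features_by_parent[p.id] = set()
        filt.false_models_by_parent[p.id] = set()
    copy_selected: dict[str, set[int]] = {}
    for i, fp in enumerate(false_pos):
        r = model.w * X[i]
        selected = set(int(n) for n in np.flatnonzero(r > cutoff))
        copy_selected[fp.id] = selected
        filt.parent_of_copy[fp.id] = fp.parent_id  # type: ignore[arg-type]

    if hits is not None:
        known_ids = set()
        significant: set[str] = set()
        for fp in false_pos:
            profile = EnrichmentProfile(
                sequence_id=fp.id,
                scores=np.array([1.0] * len(copy_selected[fp.id])),
                index=np.array(sorted(copy_selected[fp.id]), dtype=np.int64),
                cutoff=0.0,
            ) if copy_selected[fp.id] else None
            if profile is None:
                continue
            for frag in build_fragments(profile, space):
                known_ids.add(frag.fragment_id)
        unknown = set(hits["fragment_id"]) - known_ids
        if unknown:
            raise ValueError(
                f"hit table references unknown fragment id(s): {sorted(unknown)[:5]}"
            )
        sig = hits[hits["p_value"] < hit_p_threshold]
        significant = set(sig["fragment_id"])
        for fp_id, selected in copy_selected.items():
            kept = set()
            for n in selected:
                frag_id = f"{fp_id}|m{space.model_of(n).decimal}"
                if frag_id in significant:
                    kept.add(n)
            copy_selected[fp_id] = kept

    for fp_id, selected in copy_selected.items():
        filt.by_copy[fp_id] = selected
        parent = filt.parent_of_copy[fp_id]
        filt.false_features_by_parent[parent] |= selected
        filt.false_models_by_parent[parent] |= {
            space.model_of(n).decimal for n in selected
        }
    return filt


def eliminate(
    profiles: TypingSequence[EnrichmentProfile],
    filt: FeatureFilter,
    space: FeatureSpace,
    mode: str = BY_MODEL,
) -> tuple[list[EnrichmentProfile], np.ndarray]:
    """Zero false enrichments per positive and derive Psi_k^h.

    by_model (default): a feature is zeroed when its gap mask was implicated
    by any of that positive's own scrambled copies.  by_feature: only exact
    feature-index matches are zeroed.  Returns the filtered profiles and the
    sorted union of surviving selected indices (the high-confidence set).
    """
    if mode not in (BY_MODEL, BY_FEATURE):
        raise ValueError(f"unknown elimination mode {mode!r}")
    out: list[EnrichmentProfile] = []
    surviving: set[int] = set()
    for profile in profiles:
        scores = profile.scores.copy()
        if not filt.is_empty:
            if profile.sequence_id not in filt.false_models_by_parent:
                raise ValueError(
                    f"positive {profile.sequence_id!r} has no scrambled copies "
                    "in the feature filter"
                )
            if mode == BY_MODEL:
                bad_models = filt.false_models_by_parent[profile.sequence_id]
                if bad_models:
                    masks = np.searchsorted(space.offsets, profile.index, side="right") - 1
                    decimals = np.array([space.masks[j].decimal for j in masks])
                    scores[np.isin(decimals, sorted(bad_models))] = 0.0
            else:
                bad = filt.false_features_by_parent[profile.sequence_id]
                if bad:
                    scores[np.isin(profile.index, sorted(bad))] = 0.0
        filtered = EnrichmentProfile(
            sequence_id=profile.sequence_id,
            scores=scores,
            index=profile.index,
            cutoff=profile.cutoff,
        )
        out.append(filtered)
        surviving.update(int(n) for n in filtered.selected)
    return out, np.array(sorted(surviving), dtype=np.int64)

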