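"""Repeated stratified cross-validation and classifier comparison.

Positives and their matched scrambled negatives are split into stratified
folds (all scrambles travel with their parent, so per-sequence composition
never leaks between train and test).  Each repeat re-randomizes the folds;
per positive we accumulate the number of repeats in which it was called
negative (its FN count).  A positive is *detected* by a method when its FN
call rate does not exceed the cutoff (default 10%, strict '>' defines a
miss).  Comparing detection by the folded and the contiguous kernel assigns
each positive to Group 1 (folded only), Group 2 (neither), Group 3 (both),
or Group 0 (contiguous only; structurally empty because the contiguous model
is a subset of the folded feature space).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence as TypingSequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from . import classifier, enrichment, seqio
from .seqio import BackgroundModel, Sequence
from .spectrum import FeatureSpace, feature_space, featurize_matrix

FOLDED = "folded"
CONTIGUOUS = "contiguous"

_RATE_EPS = 1e-12  # guards float artifacts in rate-cutoff comparisons


@dataclass
class CVConfig:
    """Cross-validation settings (defaults follow the study design)."""

    folds: int = 10
    repeats: int = 100
    fn_cutoff_rate: float = 0.10
    seed: int = 0
    apply_feature_elimination: bool = False
    kernel: str = FOLDED
    k: int = 6
    C: float = 1.0
    cutoff: float = enrichment.DEFAULT_CUTOFF
    pseudocount: float = 1.0
    n_scrambles_fe: int = 10
    elimination_mode: str = enrichment.BY_MODEL

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.fn_cutoff_rate < 1:
            raise ValueError("fn_cutoff_rate must be in (0, 1)")
        if self.kernel not in (FOLDED, CONTIGUOUS):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class CVResult:
    """Per-sequence FN/FP counts and per-repeat ROC/PR summaries."""

    repeats: int
    fn_counts: dict[str, int]
    fp_counts: dict[str, int]
    per_repeat_auc: list[float]
    per_repeat_aucpr: list[float]
    roc_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    pr_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def auc_avg(self) -> float:
        return float(np.mean(self.per_repeat_auc))

    @property
    def aucpr_avg(self) -> float:
        return float(np.mean(self.per_repeat_aucpr))


@dataclass
class GroupAssignment:
    """Partition of the positives by which kernel detects them."""

    group1: frozenset[str]  # folded only
    group2: frozenset[str]  # neither
    group3: frozenset[str]  # both
    group0: frozenset[str]  # contiguous only (expected empty)


def stratified_folds(
    labels: TypingSequence[int] | np.ndarray, folds: int, seed: int
) -> np.ndarray:
    """Fold id per example, class proportions within +-1 of global.

    Each class is shuffled and dealt round-robin; deterministic per seed.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=np.int64)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if folds > len(idx):
            raise ValueError(
                f"cannot make {folds} folds from {len(idx)} examples of class {cls}"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def grouped_folds(
    sequences: TypingSequence[Sequence], folds: int, seed: int
) -> np.ndarray:
    """Fold id per sequence with scrambles pinned to their parent's fold."""
    pos_ids = [s.id for s in sequences if s.label == 1]
    if folds > len(pos_ids):
        raise ValueError(f"cannot make {folds} folds from {len(pos_ids)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos_ids))
    fold_of_parent = {pos_ids[j]: int(i % folds) for i, j in enumerate(order)}
    assignment = np.empty(len(sequences), dtype=np.int64)
    orphans = []
    for i, s in enumerate(sequences):
        if s.label == 1:
            assignment[i] = fold_of_parent[s.id]
        elif s.parent_id in fold_of_parent:
            assignment[i] = fold_of_parent[s.parent_id]
        else:
            orphans.append(i)
    for j, i in enumerate(orphans):  # negatives without a parent: round-robin
        assignment[i] = j % folds
    return assignment


def roc_pr(
    scores: TypingSequence[float] | np.ndarray,
    labels: TypingSequence[int] | np.ndarray,
) -> dict:
    """ROC and PR curves with trapezoidal areas; ties share a threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute ROC/PR")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    precision, recall, _ = precision_recall_curve(labels, scores, pos_label=1)
    # precision_recall_curve returns recall in decreasing order
    aucpr = float(_trapezoid_auc(recall[::-1], precision[::-1]))
    return {
        "roc": (fpr, tpr),
        "pr": (recall[::-1], precision[::-1]),
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "aucpr": aucpr,
    }


def _kernel_matrix(X_full: np.ndarray, space: FeatureSpace, kernel: str) -> np.ndarray:
    if kernel == FOLDED:
        return X_full
    return X_full[:, space.contiguous_slice]


def _run_once(
    sequences: TypingSequence[Sequence],
    X: np.ndarray,
    space: FeatureSpace,
    bg: BackgroundModel,
    config: CVConfig,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One complete CV pass: returns (labels, decision scores, predictions)."""
    y = np.array([s.label for s in sequences], dtype=np.float64)
    assignment = grouped_folds(sequences, config.folds, fold_seed)
    scores = np.empty(len(sequences), dtype=np.float64)
    for fold in range(config.folds):
        test = assignment == fold
        train_idx = np.flatnonzero(~test)
        test_idx = np.flatnonzero(test)
        X_train, y_train = X[train_idx], y[train_idx]
        X_test = X[test_idx]
        columns: np.ndarray | None = None
        if config.apply_feature_elimination:
            columns = _training_fold_psi(
                [sequences[i] for i in train_idx], X_train, y_train, space, bg, config,
                fold_seed + fold,
            )
            X_train = X_train[:, columns]
            X_test = X_test[:, columns]
        model = classifier.train(X_train, y_train, C=config.C, seed=config.seed)
        scores[test_idx] = X_test @ model.w + model.b
    preds = np.where(scores > 0, 1.0, -1.0)
    return y, scores, preds


def _training_fold_psi(
    train_seqs: list[Sequence],
    X_train: np.ndarray,
    y_train: np.ndarray,
    space: FeatureSpace,
    bg: BackgroundModel,
    config: CVConfig,
    seed: int,
) -> np.ndarray:
    """High-confidence column set Psi_k^h derived from the training folds only."""
    base = classifier.train(X_train, y_train, C=config.C, seed=config.seed)
    pos_rows = np.flatnonzero(y_train > 0)
    profiles = [
        enrichment.EnrichmentProfile(
            sequence_id=train_seqs[i].id,
            scores=base.w * X_train[i],
            index=np.arange(X_train.shape[1], dtype=np.int64),
            cutoff=config.cutoff,
        )
        for i in pos_rows
    ]
    filt = enrichment.discover_false_features(
        [train_seqs[i] for i in pos_rows],
        space,
        n_scrambles=config.n_scrambles_fe,
        C=config.C,
        cutoff=config.cutoff,
        seed=seed,
        bg=bg,
        pseudocount=config.pseudocount,
    )
    _, psi = enrichment.eliminate(profiles, filt, space, mode=config.elimination_mode)
    if len(psi) == 0:
        # degenerate: nothing survives; fall back to the unrestricted space
        return np.arange(X_train.shape[1], dtype=np.int64)
    return psi


def run_cv_once(
    sequences: TypingSequence[Sequence],
    config: CVConfig,
    space: FeatureSpace | None = None,
    bg: BackgroundModel | None = None,
) -> dict:
    """A single 10-fold pass; every sequence is tested exactly once."""
    space = space or feature_space(config.k)
    bg = bg or seqio.build_background(sequences, config.k, config.pseudocount)
    X_full = featurize_matrix(sequences, space, bg)
    X = _kernel_matrix(X_full, space, config.kernel)
    y, scores, preds = _run_once(sequences, X, space, bg, config, config.seed)
    return {
        "ids": [s.id for s in sequences],
        "labels": y,
        "scores": scores,
        "predictions": preds,
    }


def repeat_cv(
    sequences: TypingSequence[Sequence],
    config: CVConfig,
    space: FeatureSpace | None = None,
    bg: BackgroundModel | None = None,
    keep_curves: bool = False,
) -> CVResult:
    """Repeated randomized CV with cumulative FN/FP accounting."""
    space = space or feature_space(config.k)
    bg = bg or seqio.build_background(sequences, config.k, config.pseudocount)
    X_full = featurize_matrix(sequences, space, bg)
    X = _kernel_matrix(X_full, space, config.kernel)
    fn_counts = {s.id: 0 for s in sequences if s.label == 1}
    fp_counts = {s.id: 0 for s in sequences if s.label == -1}
    aucs, aucprs = [], []
    roc_curves, pr_curves = [], []
    for r in range(config.repeats):
        fold_seed = int(
            np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2**31)
        )
        y, scores, preds = _run_once(sequences, X, space, bg, config, fold_seed)
        for s, yi, pi in zip(sequences, y, preds):
            if yi > 0 and pi < 0:
                fn_counts[s.id] += 1
            elif yi < 0 and pi > 0:
                fp_counts[s.id] += 1
        curves = roc_pr(scores, y)
        aucs.append(curves["auc"])
        aucprs.append(curves["aucpr"])
        if keep_curves:
            roc_curves.append(curves["roc"])
            pr_curves.append(curves["pr"])
    return CVResult(
        repeats=config.repeats,
        fn_counts=fn_counts,
        fp_counts=fp_counts,
        per_repeat_auc=aucs,
        per_repeat_aucpr=aucprs,
        roc_curves=roc_curves,
        pr_curves=pr_curves,
    )


def detected(fn_count: int, repeats: int, rate_cutoff: float = 0.10) -> bool:
    """A positive is detected unless its FN call rate exceeds the cutoff.

    The boundary (e.g. FN = 10/100 at a 10% cutoff) still counts as detected:
    only a rate strictly above the cutoff is a miss.
    """
    return fn_count / repeats <= rate_cutoff + _RATE_EPS


def assign_groups(
    fn_folded: Mapping[str, int],
    fn_contiguous: Mapping[str, int],
    repeats: int,
    rate_cutoff: float = 0.10,
) -> GroupAssignment:
    """Partition positives by which kernel detects them."""
    if set(fn_folded) != set(fn_contiguous):
        raise ValueError("FN maps cover different positive id sets")
    g1, g2, g3, g0 = set(), set(), set(), set()
    for sid in fn_folded:
        df = detected(fn_folded[sid], repeats, rate_cutoff)
        dc = detected(fn_contiguous[sid], repeats, rate_cutoff)
        if df and not dc:
            g1.add(sid)
        elif not df and not dc:
            g2.add(sid)
        elif df and dc:
            g3.add(sid)
        else:
            g0.add(sid)
    return GroupAssignment(
        group1=frozenset(g1),
        group2=frozenset(g2),
        group3=frozenset(g3),
        group0=frozenset(g0),
    )
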