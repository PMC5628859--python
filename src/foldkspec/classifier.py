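"""Soft-margin linear SVM over explicit folded-spectrum features.

The quadratic program is delegated to libsvm (via scikit-learn) on a
precomputed linear Gram matrix — since the feature map is explicit, the
linear kernel inner product equals the dot product of folded vectors.  The
primal weight vector is reconstructed from the dual solution as
w = sum_i y_i alpha_i x_i, which is what the enrichment analysis consumes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as TypingSequence

import numpy as np
from sklearn.svm import SVC

from .spectrum import SpectrumVector


@dataclass
class TrainedModel:
    """Learned weight vector, bias, and the feature index set trained on."""

    w: np.ndarray
    b: float
    active_index: np.ndarray | None  # None = full feature space
    C: float
    seed: int
    n_pos: int
    n_neg: int

    @property
    def n_features(self) -> int:
        return len(self.w)


def _as_matrix(
    X: TypingSequence[SpectrumVector] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=np.float64), None
    idx0 = X[0].active_index
    for v in X[1:]:
        same = (
            (v.active_index is None and idx0 is None)
            or (
                v.active_index is not None
                and idx0 is not None
                and np.array_equal(v.active_index, idx0)
            )
        )
        if not same:
            raise ValueError("all training vectors must share one active index set")
    return np.vstack([v.values for v in X]), idx0


def train(
    X: TypingSequence[SpectrumVector] | np.ndarray,
    y: TypingSequence[int] | np.ndarray,
    C: float = 1.0,
    seed: int = 0,
    active_index: np.ndarray | None = None,
    tol: float = 1e-6,
) -> TrainedModel:
    """Fit a soft-margin linear SVM on explicit feature vectors.

    X may be a list of SpectrumVector (sharing one active index) or a
    pre-stacked (n, d) array.  Labels are +1/-1 and both classes must be
    present.  Deterministic given the data and solver tolerance.
    """
    mat, idx = _as_matrix(X)
    if active_index is None:
        active_index = idx
    y = np.asarray(y, dtype=np.float64)
    if len(mat) != len(y):
        raise ValueError("X and y lengths differ")
    if len(mat) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires examples from both classes")
    gram = mat @ mat.T
    svc = SVC(kernel="precomputed", C=C, tol=tol, cache_size=256)
    svc.fit(gram, y)
    # dual_coef_ holds y_i * alpha_i for the support vectors
    w = (svc.dual_coef_ @ mat[svc.support_]).ravel()
    return TrainedModel(
        w=w,
        b=float(svc.intercept_[0]),
        active_index=None if active_index is None else np.asarray(active_index),
        C=C,
        seed=seed,
        n_pos=int((y > 0).sum()),
        n_neg=int((y < 0).sum()),
    )


def _check_index(model: TrainedModel, x: SpectrumVector | np.ndarray) -> np.ndarray:
    if isinstance(x, np.ndarray):
        values = np.asarray(x, dtype=np.float64)
    else:
        same = (
            (x.active_index is None and model.active_index is None)
            or (
                x.active_index is not None
                and model.active_index is not None
                and np.array_equal(x.active_index, model.active_index)
            )
        )
        if not same:
            raise ValueError("vector active index does not match the trained model")
        values = x.values
    if values.shape != model.w.shape:
        raise ValueError(
            f"feature dimension {values.shape} does not match model {model.w.shape}"
        )
    return values


def decision(model: TrainedModel, x: SpectrumVector | np.ndarray) -> float:
    """Signed distance-like score f(x) = w.x + b."""
    return float(model.w @ _check_index(model, x) + model.b)


def predict(model: TrainedModel, x: SpectrumVector | np.ndarray) -> int:
    """Class label from the sign of the decision value (ties -> -1)."""
    return 1 if decision(model, x) > 0 else -1


def save_model(
    model: TrainedModel, path, feature_names: TypingSequence[str] | None = None
) -> None:
    """Serialize as TSV of (feature pattern, weight) with a metadata header."""
    idx = (
        model.active_index
        if model.active_index is not None
        else np.arange(model.n_features)
    )
    index_hash = int(np.int64(np.sum(idx * 2654435761)) & 0x7FFFFFFF)
    with open(path, "w") as handle:
        handle.write(
            f"#b={model.b!r}\tC={model.C!r}\tn_pos={model.n_pos}\t"
            f"n_neg={model.n_neg}\tindex_hash={index_hash}\n"
        )
        for i, g in enumerate(idx):
            name = feature_names[i] if feature_names is not None else str(int(g))
            handle.write(f"{name}\t{model.w[i]:.9g}\n")
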