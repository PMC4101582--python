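"""Soft-margin linear SVM on meta-data, binary and one-against-one.

The binary classifier is the standard C-SVM: minimize
``1/2 ||w||^2 + C sum_i xi_i`` subject to ``c_i (w.y_i + b) >= 1 - xi_i``,
solved in the dual where only samples with ``alpha_i > 0`` (the support
vectors) enter the decision function
``f(y') = sign(sum_i alpha_i c_i (y_i . y') + b)``.
The kernel is fixed linear.  Multiclass problems train one binary model
per unordered class pair and predict by max-wins voting.

The quadratic program is solved by scikit-learn's SVC (libsvm SMO); this
module exposes the solution in primal/dual form (alphas, support
vectors, bias, normal ``w``) so the KKT invariants can be checked
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .io import SpectraMatrix

__all__ = [
    "SvmModel",
    "MulticlassModel",
    "train_binary",
    "decision_values",
    "predict_binary",
    "train_multiclass",
    "predict_multiclass",
]


def _as_matrix(samples) -> np.ndarray:
    if isinstance(samples, SpectraMatrix):
        return samples.intensities
    return np.atleast_2d(np.asarray(samples, dtype=float))


@dataclass
class SvmModel:
    """A fitted maximum-margin hyperplane in dual and primal form.

    ``support_alphas`` holds the nonzero Lagrange multipliers
    ``0 < alpha_i <= C``; ``normal_w = sum_i alpha_i c_i y_i``.  Slack
    variables are solver-internal and surface only as training hinge
    losses in diagnostics.
    """

    support_alphas: np.ndarray
    support_vectors: np.ndarray
    support_labels: np.ndarray
    bias: float
    cost_C: float
    normal_w: np.ndarray
    kernel: str = "linear"

    def dual_objective(self) -> float:
        a, c, Y = self.support_alphas, self.support_labels, self.support_vectors
        G = (Y @ Y.T) * np.outer(a * c, a * c)
        return float(a.sum() - 0.5 * G.sum())

    def primal_norm_sq(self) -> float:
        return float(self.normal_w @ self.normal_w)

    def hinge_losses(self, samples, labels) -> np.ndarray:
        d = decision_values(self, samples)
        return np.maximum(0.0, 1.0 - np.asarray(labels) * d)


@dataclass
class MulticlassModel:
    """One binary model per unordered class pair (one-against-one)."""

    class_set: list
    pairwise_models: dict  # (class_i, class_j), i < j -> SvmModel

    def __post_init__(self) -> None:
        k = len(self.class_set)
        if len(self.pairwise_models) != k * (k - 1) // 2:
            raise ValueError("expected k(k-1)/2 pairwise models")


def train_binary(meta, labels, C: float = 1.0) -> SvmModel:
    """Fit the linear C-SVM on +/-1 labelled meta-samples."""
    X = _as_matrix(meta)
    y = np.asarray(labels, dtype=float)
    if C <= 0:
        raise ValueError("C must be positive")
    present = set(np.unique(y).tolist())
    if present != {-1.0, 1.0}:
        raise ValueError(f"labels must contain both classes -1 and +1, got {present}")
    clf = SVC(kernel="linear", C=C, tol=1e-6)
    clf.fit(X, y)
    # sklearn orders classes [-1, +1]; dual_coef_[0] = alpha_i * c_i
    dual = clf.dual_coef_[0]
    sv = clf.support_vectors_
    sv_labels = y[clf.support_]
    alphas = dual * sv_labels  # alpha_i >= 0
    w = dual @ sv
    return SvmModel(
        support_alphas=alphas,
        support_vectors=sv,
        support_labels=sv_labels,
        bias=float(clf.intercept_[0]),
        cost_C=float(C),
        normal_w=w,
    )


def decision_values(model: SvmModel, samples) -> np.ndarray:
    """``sum_i alpha_i c_i (y_i . y') + b`` per sample."""
    X = _as_matrix(samples)
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"sample dimension {X.shape[1]} != "
            f"training dimension {model.support_vectors.shape[1]}"
        )
    coef = model.support_alphas * model.support_labels
    return X @ model.support_vectors.T @ coef + model.bias


def predict_binary(model: SvmModel, samples) -> np.ndarray:
    """Sign of the decision value; an exact 0 resolves to +1."""
    d = decision_values(model, samples)
    return np.where(d >= 0, 1, -1)


def train_multiclass(meta, labels, C: float = 1.0) -> MulticlassModel:
    """One-against-one training over all class pairs.

    Within a pair the lexicographically smaller class code maps to +1.
    """
    import warnings

    X = _as_matrix(meta)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 3:
            warnings.warn(f"class {c!r} has fewer than 3 samples", stacklevel=2)
    models = {}
    for ci, cj in combinations(classes, 2):
        mask = (y == ci) | (y == cj)
        pair_y = np.where(y[mask] == ci, 1, -1)
        models[(ci, cj)] = train_binary(X[mask], pair_y, C)
    return MulticlassModel(classes, models)


def predict_multiclass(model: MulticlassModel, samples) -> np.ndarray:
    """Max-wins voting over the pairwise decision functions.

    Ties on vote count break to the largest summed |decision value| among
    the tied classes, then to the lowest class code.
    """
    X = _as_matrix(samples)
    n = X.shape[0]
    classes = model.class_set
    votes = {c: np.zeros(n) for c in classes}
    strength = {c: np.zeros(n) for c in classes}
    for (ci, cj), m in model.pairwise_models.items():
        d = decision_values(m, X)
        wins_i = d >= 0
        votes[ci] += wins_i
        votes[cj] += ~wins_i
        strength[ci] += np.abs(d)
        strength[cj] += np.abs(d)
    out = []
    for s in range(n):
        best = max(
            classes,
            key=lambda c: (votes[c][s], strength[c][s], _inv_order(classes, c)),
        )
        out.append(best)
    return np.array(out)


def _inv_order(classes, c):
    # lowest class code wins the final tie-break -> highest key
    return -classes.index(c)
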