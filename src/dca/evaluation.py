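"""Repeated stratified k-fold cross-validation harness.

Compares three pipelines on one labelled panel:

``dca_svm``
    Derivative-component denoising followed by a linear SVM.  In the
    default *transductive* mode the transform is fitted once on the full
    panel before splitting (the conventional usage for this method); in
    *inductive* mode it is refitted on each training split and applied
    to the held-out fold, so no test information reaches the fit.
``svm``
    Plain linear SVM on the raw intensities.
``fs_svm``
    Univariate filter (two-sample t-test for binary labels, one-way
    ANOVA for k > 2) keeping channels with p < 0.05, then a linear SVM.

Metrics follow the usual confusion-matrix definitions: sensitivity
``TP/(TP+FN)``, specificity ``TN/(TN+FP)``, positive prediction ratio
``TP/(TP+FP)``.  For multiclass labels accuracy is plain top-1; the
binary metrics are computed only under an explicit binarization map that
is recorded in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import __version__ as _pkg_version
from .biomarker import _columnwise_stats
from .core import DCAConfig, apply_model, fit_transform
from .io import SpectraMatrix
from .svm import (
    predict_binary,
    predict_multiclass,
    train_binary,
    train_multiclass,
)

__all__ = [
    "ConfusionCounts",
    "stratified_folds",
    "binarize",
    "metrics",
    "cross_validate",
]

METHODS = ("dca_svm", "svm", "fs_svm")


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts for one evaluated fold."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true)
        p = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((t == 1) & (p == 1))),
            TN=int(np.sum((t == -1) & (p == -1))),
            FP=int(np.sum((t == -1) & (p == 1))),
            FN=int(np.sum((t == 1) & (p == -1))),
        )


def metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity and PPV from one fold's counts.

    A zero denominator yields NaN with a warning rather than an error.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return {
        "accuracy": (counts.TP + counts.TN) / counts.total,
        "sensitivity": ratio(counts.TP, counts.TP + counts.FN, "sensitivity"),
        "specificity": ratio(counts.TN, counts.TN + counts.FP, "specificity"),
        "ppv": ratio(counts.TP, counts.TP + counts.FP, "ppv"),
    }


def stratified_folds(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of k class-stratified folds.

    Deterministic given the seed; per-class counts across folds differ by
    at most one.  A class smaller than k is an error.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def binarize(labels, positive_set) -> np.ndarray:
    """Map classes in ``positive_set`` to +1 and the rest to -1."""
    y = np.asarray(labels)
    classes = set(y.tolist())
    pos = set(positive_set)
    if not pos or not pos < classes:
        raise ValueError(
            "positive_set must be a nonempty proper subset of the classes"
        )
    return np.where(np.isin(y, sorted(pos)), 1, -1)


def _fs_filter(X, y, alpha: float):
    _, p, _ = _columnwise_stats(X, y, pooled=False)
    keep = p < alpha
    if not keep.any():
        warnings.warn(
            "feature filter kept no channels; falling back to all",
            stacklevel=3,
        )
        keep = np.ones_like(keep)
    return keep


def cross_validate(
    spectra: SpectraMatrix,
    labels=None,
    methods=("dca_svm", "svm"),
    config: DCAConfig | None = None,
    C: float = 1.0,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    positive_set=None,
    alpha: float = 0.05,
) -> dict:
    """Run repeated stratified k-fold CV and aggregate per-method metrics.

    Returns a JSON-serializable report: per repeat x fold metrics and
    confusion counts, plus mean and standard deviation per metric per
    method, with the full run configuration in the metadata.  Identical
    seed and configuration reproduce the report byte-for-byte.
    """
    config = config or DCAConfig()
    y = spectra.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ValueError("labels are required")
    methods = tuple(methods)
    if not methods:
        raise ValueError("at least one method is required")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}")

    classes = sorted(set(y.tolist()))
    binary = len(classes) == 2
    if binary:
        # smaller class code -> +1, mirroring the pairwise convention
        y_pm = np.where(y == classes[0], 1, -1)
        bin_map = {str(classes[0]): 1, str(classes[1]): -1}
    elif positive_set is not None:
        bin_map = {
            str(c): (1 if c in set(positive_set) else -1) for c in classes
        }
    else:
        bin_map = None

    X = spectra.intensities
    transductive = config.fit_mode == "transductive"
    meta_full = None
    fs_keep_full = None
    if "dca_svm" in methods and transductive:
        meta_full = fit_transform(spectra, config)[0].intensities
    if "fs_svm" in methods and transductive:
        fs_keep_full = _fs_filter(X, y, alpha)

    folds_log = []
    per_method: dict[str, list[dict]] = {m: [] for m in methods}
    for rep in range(repeats):
        rep_seed = seed + rep
        assignment = stratified_folds(y, k=k, seed=rep_seed)
        folds_log.append(assignment.tolist())
        for fold in range(k):
            test = assignment == fold
            train = ~test
            for method in methods:
                Xtr, Xte = _method_views(
                    method, spectra, X, y, train, test, config,
                    meta_full, fs_keep_full, alpha,
                )
                if binary:
                    model = train_binary(Xtr, y_pm[train], C=C)
                    pred = predict_binary(model, Xte)
                    counts = ConfusionCounts.from_predictions(y_pm[test], pred)
                    rec = dict(metrics(counts))
                    rec["confusion"] = vars(counts).copy()
                else:
                    model = train_multiclass(Xtr, y[train], C=C)
                    pred = predict_multiclass(model, Xte)
                    rec = {"accuracy": float(np.mean(pred == y[test]))}
                    if bin_map is not None:
                        t_pm = np.array([bin_map[str(v)] for v in y[test]])
                        p_pm = np.array([bin_map[str(v)] for v in pred])
                        counts = ConfusionCounts.from_predictions(t_pm, p_pm)
                        for name, v in metrics(counts).items():
                            if name != "accuracy":
                                rec[name] = v
                        rec["confusion"] = vars(counts).copy()
                rec.update(repeat=rep, fold=fold, n_test=int(test.sum()))
                per_method[method].append(rec)

    report = {
        "schema_version": "1",
        "metadata": {
            "package_version": _pkg_version,
            "seed": seed,
            "k": k,
            "repeats": repeats,
            "C": C,
            "n_samples": spectra.n_samples,
            "n_channels": spectra.n_channels,
            "classes": [str(c) for c in classes],
            "binarization": bin_map,
            "fit_mode": config.fit_mode,
            "dca": {
                "wavelet": config.wavelet.wavelet_name,
                "level_J": config.wavelet.level_J,
                "boundary_mode": config.wavelet.boundary_mode,
                "cutoff_tau": config.cutoff_tau,
                "n_components": config.n_components,
                "ratio_threshold": config.ratio_threshold,
            },
            "fs_alpha": alpha,
        },
        "methods": {},
    }
    for method in methods:
        records = per_method[method]
        agg = {}
        for name in records[0]:
            if name in ("repeat", "fold", "n_test", "confusion"):
                continue
            vals = np.array([r[name] for r in records], dtype=float)
            vals = vals[np.isfinite(vals)]
            agg[name] = {
                "mean": round(float(vals.mean()), 12) if vals.size else None,
                "sd": round(float(vals.std(ddof=1)), 12)
                if vals.size > 1
                else 0.0,
            }
        report["methods"][method] = {
            "folds": [_jsonify(r) for r in records],
            "aggregate": agg,
        }
    return report


def _method_views(
    method, spectra, X, y, train, test, config, meta_full, fs_keep_full, alpha
):
    """Training/test design matrices for one method on one split."""
    if method == "svm":
        return X[train], X[test]
    if method == "dca_svm":
        if config.fit_mode == "transductive":
            return meta_full[train], meta_full[test]
        sub = SpectraMatrix(
            X[train],
            spectra.mz,
            [spectra.sample_ids[i] for i in np.flatnonzero(train)],
            y[train],
        )
        meta_tr, model = fit_transform(sub, config)
        te = SpectraMatrix(
            X[test],
            spectra.mz,
            [spectra.sample_ids[i] for i in np.flatnonzero(test)],
        )
        meta_te = apply_model(model, te)
        return meta_tr.intensities, meta_te.intensities
    if method == "fs_svm":
        keep = (
            fs_keep_full
            if config.fit_mode == "transductive"
            else _fs_filter(X[train], y[train], alpha)
        )
        return X[train][:, keep], X[test][:, keep]
    raise ValueError(f"unknown method {method!r}")


def _jsonify(rec: dict) -> dict:
    out = {}
    for k_, v in rec.items():
        if isinstance(v, float):
            out[k_] = None if not np.isfinite(v) else round(v, 12)
        else:
            out[k_] = v
    return out
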