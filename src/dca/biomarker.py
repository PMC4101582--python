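"""Biomarker ranking on meta-data: t / F statistics per channel.

Every m/z channel of the de-noised panel is scored by a two-sample
t-statistic (binary labels) or a one-way F-statistic (k > 2 classes),
ranked by statistic (descending; equivalently p ascending), and the
top-k channels reported as candidate biomarkers.  A linear SVM with a
large cost on just those channels checks whether they already make the
classes linearly separable.

The t-statistic is the absolute-value form
``t = |xbar - ybar| / sqrt(sx^2/n1 + sy^2/n2)`` (Welch) with a pooled
variance variant ``s_p^2 = ((n1-1)sx^2 + (n2-1)sy^2)/(n1+n2-2)``
available; p-values are two-sided and uncorrected by default
(Benjamini-Hochberg behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SpectraMatrix
from .svm import (
    predict_binary,
    predict_multiclass,
    train_binary,
    train_multiclass,
)

__all__ = [
    "GroupStats",
    "t_statistic",
    "f_statistic",
    "rank_biomarkers",
    "separability_check",
]


@dataclass
class GroupStats:
    """Per-class sizes, means and unbiased variances for one feature."""

    sizes: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.sizes.sum())

    @property
    def grand_mean(self) -> float:
        return float((self.sizes * self.means).sum() / self.n_total)

    @property
    def pooled_variance(self) -> float:
        if self.sizes.size != 2:
            raise ValueError("pooled variance is defined for two groups")
        (n1, n2), (v1, v2) = self.sizes, self.variances
        return float(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))

    @classmethod
    def from_groups(cls, groups: list[np.ndarray]) -> "GroupStats":
        return cls(
            sizes=np.array([len(g) for g in groups]),
            means=np.array([np.mean(g) for g in groups]),
            variances=np.array([np.var(g, ddof=1) for g in groups]),
        )


def _split_groups(values, labels) -> list[np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    groups = [v[y == c] for c in classes]
    for c, g in zip(classes, groups):
        if g.size < 2:
            raise ValueError(f"group {c!r} has fewer than 2 observations")
    return groups


def t_statistic(values, labels, pooled: bool = False) -> tuple[float, float]:
    """Absolute two-sample t and its two-sided p-value.

    Welch by default (Welch-Satterthwaite df); ``pooled=True`` uses the
    pooled variance with ``n1 + n2 - 2`` df.  Two identical constant
    groups give (0, 1); distinct constant groups give (inf, 0).
    """
    groups = _split_groups(values, labels)
    if len(groups) != 2:
        raise ValueError(f"t-statistic needs 2 classes, got {len(groups)}")
    gs = GroupStats.from_groups(groups)
    (n1, n2), (m1, m2), (v1, v2) = gs.sizes, gs.means, gs.variances
    diff = abs(m1 - m2)
    if pooled:
        se2 = gs.pooled_variance * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2
    if se2 == 0:
        return (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
    t = diff / np.sqrt(se2)
    p = 2.0 * stats.t.sf(t, df)
    return float(t), float(min(p, 1.0))


def f_statistic(values, labels) -> tuple[float, float]:
    """One-way ANOVA F over k >= 2 groups and its p-value.

    ``F = [sum_j n_j (xbar_j - grand)^2 / (k-1)] /
    [sum_j (n_j - 1) s_j^2 / (n_T - k)]``; identical constant groups
    give (0, 1), zero within-group variance with distinct means (inf, 0).
    """
    groups = _split_groups(values, labels)
    k = len(groups)
    gs = GroupStats.from_groups(groups)
    grand = gs.grand_mean
    ss_between = float((gs.sizes * (gs.means - grand) ** 2).sum())
    ss_within = float(((gs.sizes - 1) * gs.variances).sum())
    df1, df2 = k - 1, gs.n_total - k
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (float("inf"), 0.0)
    F = (ss_between / df1) / (ss_within / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def _columnwise_stats(X, labels, pooled):
    """Vectorized per-channel t or F over a panel. Returns (stat, p, kind)."""
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    k = len(classes)
    sizes = np.array([np.sum(y == c) for c in classes], dtype=float)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    variances = np.stack([X[y == c].var(axis=0, ddof=1) for c in classes])
    with np.errstate(divide="ignore", invalid="ignore"):
        if k == 2:
            (n1, n2), (m1, m2), (v1, v2) = sizes, means, variances
            diff = np.abs(m1 - m2)
            if pooled:
                sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
                se2 = sp2 * (1 / n1 + 1 / n2)
                df = np.full(X.shape[1], n1 + n2 - 2)
            else:
                se2 = v1 / n1 + v2 / n2
                df = se2**2 / (
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                )
            stat = diff / np.sqrt(se2)
            p = 2.0 * stats.t.sf(stat, df)
            kind = "t"
        else:
            grand = (sizes[:, None] * means).sum(axis=0) / sizes.sum()
            ssb = (sizes[:, None] * (means - grand) ** 2).sum(axis=0)
            ssw = ((sizes[:, None] - 1) * variances).sum(axis=0)
            df1, df2 = k - 1, int(sizes.sum()) - k
            stat = (ssb / df1) / (ssw / df2)
            p = stats.f.sf(stat, df1, df2)
            kind = "F"
    degenerate = ~np.isfinite(stat)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance channel(s) scored 0",
            stacklevel=3,
        )
        stat = np.where(degenerate, 0.0, stat)
        p = np.where(degenerate, 1.0, p)
    return stat, np.clip(p, 0.0, 1.0), kind


def rank_biomarkers(
    meta: SpectraMatrix,
    labels=None,
    top_k: int = 3,
    pooled: bool = False,
    correct: bool = False,
) -> pd.DataFrame:
    """Score every channel and return the top-k ranked table.

    Columns: rank, channel (1-based), mz, statistic, p_value, kind.
    Binary labels use the t-statistic, k > 2 classes the F-statistic.
    Ties in the statistic rank the lower channel index first.
    ``correct=True`` applies Benjamini-Hochberg to the p-values.
    """
    y = meta.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ValueError("labels are required for biomarker ranking")
    if not 1 <= top_k <= meta.n_channels:
        raise ValueError(f"top_k={top_k} outside [1, {meta.n_channels}]")
    stat, p, kind = _columnwise_stats(meta.intensities, y, pooled)
    if correct:
        p = _benjamini_hochberg(p)
    order = np.lexsort((np.arange(stat.size), -stat))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, stat.size + 1),
            "channel": order + 1,
            "mz": meta.mz[order],
            "statistic": stat[order],
            "p_value": p[order],
            "kind": kind,
        }
    )
    table.attrs["pooled"] = pooled
    table.attrs["corrected"] = correct
    return table.head(top_k).reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def separability_check(
    meta: SpectraMatrix,
    labels=None,
    table: pd.DataFrame | None = None,
    top_k: int = 3,
    C: float = 1e6,
) -> dict:
    """Train a large-C linear SVM on the top-k biomarker channels only.

    Returns training accuracy, a ``separable`` flag (accuracy exactly 1),
    and the per-sample coordinates on those channels for external 3-D
    plotting.
    """
    y = meta.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ValueError("labels are required")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if table is None:
        table = rank_biomarkers(meta, y, top_k=top_k)
    channels = table["channel"].to_numpy()[:top_k] - 1
    X = meta.intensities[:, channels]
    classes = sorted(set(np.asarray(y).tolist()))
    if len(classes) == 2:
        pm = np.where(np.asarray(y) == classes[0], 1, -1)
        model = train_binary(X, pm, C=C)
        pred = predict_binary(model, X)
        acc = float(np.mean(pred == pm))
    else:
        model = train_multiclass(X, y, C=C)
        pred = predict_multiclass(model, X)
        acc = float(np.mean(pred == np.asarray(y)))
    coords = pd.DataFrame(
        X, columns=[f"mz_{meta.mz[c]:g}" for c in channels]
    )
    coords.insert(0, "sample_id", meta.sample_ids)
    coords["label"] = np.asarray(y)
    return {
        "training_accuracy": acc,
        "separable": acc == 1.0,
        "channels": (channels + 1).tolist(),
        "coords": coords,
    }
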