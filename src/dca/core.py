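"""Derivative component analysis: wavelet-domain rank reduction.

The transform decomposes every spectrum into dyadic frequency bands,
replaces each *fine* detail matrix (levels ``1..tau``) by its rank-m PCA
reconstruction across samples, keeps coarse bands and the approximation
intact, and inverts the transform.  The result — the *meta-data* — has
the same shape as the input but with the fine bands compressed onto the
few directions that carry shared, high-variance structure; independent
per-channel noise, which spreads its variance over all directions, is
suppressed.

PCA orientation: observations are samples (rows), variables are
coefficient positions.  Each fine-level matrix is centered by its
per-coefficient mean over samples, reduced by truncated SVD, and the
mean added back.  The number of retained components is either fixed
(``n_components``, default 1) or chosen as the smallest ``m`` whose
variability-explanation ratio reaches ``ratio_threshold``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import SpectraMatrix
from .wavelet import (
    ConfigError,
    WaveletConfig,
    WaveletDecomposition,
    decompose,
    reconstruct,
)

__all__ = [
    "DCAConfig",
    "EigenSpectrum",
    "DCALevelModel",
    "DCAModel",
    "variability_ratio",
    "rank_reduce_detail",
    "fit_transform",
    "apply_model",
]

log = logging.getLogger(__name__)

#: MetaData is structurally a SpectraMatrix (same mz axis, ids, labels).
MetaData = SpectraMatrix


@dataclass(frozen=True)
class DCAConfig:
    """Tuning parameters of the transform.

    Parameters
    ----------
    wavelet
        Wavelet family, level ``J`` and boundary mode.  Default 'db8' at
        ``J = 7``, the uniform setting used for serum profiles.
    cutoff_tau
        Deepest level treated as fine and rank-reduced; levels beyond it
        pass through unchanged.  ``tau = 0`` disables reduction entirely
        (identity transform).
    n_components
        Number of principal components kept per fine level (default 1).
    ratio_threshold
        If set (fraction in (0, 1]), overrides ``n_components``: the
        smallest m whose variability-explanation ratio reaches the
        threshold is used per level.  The customary choice is 0.60.
    fit_mode
        'transductive' fits the per-level PCA on the full panel before
        any train/test split; 'inductive' restricts fitting to training
        data (see the evaluation harness).
    """

    wavelet: WaveletConfig = field(
        default_factory=lambda: WaveletConfig("db8", 7)
    )
    cutoff_tau: int = 2
    n_components: int = 1
    ratio_threshold: float | None = None
    fit_mode: str = "transductive"

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff_tau <= self.wavelet.level_J:
            raise ConfigError(
                f"cutoff_tau={self.cutoff_tau} outside [0, J={self.wavelet.level_J}]"
            )
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.ratio_threshold is not None and not 0 < self.ratio_threshold <= 1:
            raise ConfigError("ratio_threshold must lie in (0, 1]")
        if self.fit_mode not in ("transductive", "inductive"):
            raise ConfigError("fit_mode must be 'transductive' or 'inductive'")

    def validate_for(self, n_channels: int) -> None:
        """Hard feasibility checks plus advisory range warnings."""
        self.wavelet.validate_for(n_channels)
        J = self.wavelet.level_J
        if not 4 <= J <= int(np.ceil(np.log2(n_channels))):
            warnings.warn(
                f"J={J} outside the recommended range "
                f"[4, ceil(log2 {n_channels})]",
                stacklevel=2,
            )
        if self.cutoff_tau != 0 and not 1 < self.cutoff_tau <= J / 2:
            warnings.warn(
                f"cutoff_tau={self.cutoff_tau} outside the recommended "
                f"range (1, J/2={J / 2}]",
                stacklevel=2,
            )


@dataclass
class EigenSpectrum:
    """Non-increasing eigenvalues of a detail-matrix covariance."""

    variances: np.ndarray

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.variances) > 1e-10 * max(1.0, self.variances[0] if self.variances.size else 1.0)):
            raise ValueError("eigenvalues must be sorted non-increasing")

    @property
    def total(self) -> float:
        return float(self.variances.sum())


def variability_ratio(spectrum: EigenSpectrum, m: int) -> float:
    """Fraction of total eigenvalue mass carried by the first m components.

    A degenerate all-zero spectrum yields 1.0 with a warning.
    """
    p = spectrum.variances.size
    if not 1 <= m <= p:
        raise ValueError(f"m={m} outside [1, {p}]")
    total = spectrum.total
    if total == 0.0:
        warnings.warn("zero total variance; ratio defined as 1.0", stacklevel=2)
        return 1.0
    return float(spectrum.variances[:m].sum() / total)


@dataclass
class DCALevelModel:
    """Fitted per-level PCA: coefficient means, loadings, eigenvalues."""

    mean_vector: np.ndarray        # length n_j
    loadings: np.ndarray           # n_j x m, orthonormal columns
    explained: EigenSpectrum
    m: int

    @property
    def explained_ratio(self) -> float:
        return variability_ratio(self.explained, self.m)


@dataclass
class DCAModel:
    """Per-fine-level models plus the configuration that produced them."""

    levels: dict[int, DCALevelModel]
    config: DCAConfig
    n_channels: int


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient each loading so its largest-magnitude entry is positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    return U, Vt


def rank_reduce_detail(
    detail: np.ndarray, m: int
) -> tuple[np.ndarray, DCALevelModel]:
    """Rank-m PCA reconstruction of one detail matrix.

    Returns ``mean + sum_{i<=m} s_i u_i v_i^T`` where the ``v_i`` are the
    leading right singular vectors of the centered matrix — the closest
    rank-m approximation in the Frobenius sense — plus the fitted level
    model (mean, loadings, eigenvalue spectrum).
    """
    D = np.asarray(detail, dtype=float)
    n, p = D.shape
    if not 1 <= m <= min(n, p):
        raise ValueError(f"m={m} outside [1, min(n, p)={min(n, p)}]")
    mean = D.mean(axis=0)
    Dc = D - mean
    U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    U, Vt = _fix_signs(U, Vt)
    reduced = (U[:, :m] * s[:m]) @ Vt[:m] + mean
    variances = s**2 / max(n - 1, 1)
    model = DCALevelModel(
        mean_vector=mean,
        loadings=Vt[:m].T.copy(),
        explained=EigenSpectrum(variances),
        m=m,
    )
    return reduced, model


def _choose_m(variances: np.ndarray, config: DCAConfig, bound: int) -> int:
    if config.ratio_threshold is None:
        return min(config.n_components, bound)
    eigs = EigenSpectrum(variances)
    for m in range(1, bound + 1):
        if variability_ratio(eigs, m) >= config.ratio_threshold:
            return m
    return bound


def fit_transform(
    spectra: SpectraMatrix, config: DCAConfig | None = None
) -> tuple[MetaData, DCAModel]:
    """Fit the transform on a panel and return (meta-data, fitted model).

    Fine levels ``1..tau`` are rank-reduced; coarser detail matrices and
    the approximation are passed through bit-identical before the inverse
    transform.
    """
    config = config or DCAConfig()
    config.validate_for(spectra.n_channels)
    decomp = decompose(spectra, config.wavelet)
    levels: dict[int, DCALevelModel] = {}
    for j in range(1, config.cutoff_tau + 1):
        D = decomp.details[j - 1]
        bound = min(D.shape)
        if config.ratio_threshold is not None:
            # eigenvalues are needed up front to pick m
            s = np.linalg.svd(D - D.mean(axis=0), compute_uv=False)
            m = _choose_m(s**2 / max(D.shape[0] - 1, 1), config, bound)
        else:
            m = min(config.n_components, bound)
        reduced, model = rank_reduce_detail(D, m)
        decomp.details[j - 1] = reduced
        levels[j] = model
        log.info(
            "DCA level %d: shape %s, m=%d, explained ratio %.4f",
            j, D.shape, m, model.explained_ratio,
        )
    X_star = reconstruct(decomp)
    meta = SpectraMatrix(
        X_star, spectra.mz, spectra.sample_ids, spectra.labels
    )
    return meta, DCAModel(levels, config, spectra.n_channels)


def apply_model(model: DCAModel, spectra: SpectraMatrix) -> MetaData:
    """Project new spectra onto a fitted model (inductive application).

    Each fine-level row is replaced by the stored mean plus its projection
    onto the stored loadings; deterministic, and idempotent on the panel
    the model was fitted to when the fit used plain truncated PCA.
    """
    if spectra.n_channels != model.n_channels:
        raise ValueError(
            f"channel count {spectra.n_channels} != fitted {model.n_channels}"
        )
    decomp = decompose(spectra, model.config.wavelet)
    for j, level in model.levels.items():
        D = decomp.details[j - 1]
        U = level.loadings
        Dc = D - level.mean_vector
        decomp.details[j - 1] = Dc @ U @ U.T + level.mean_vector
    X_star = reconstruct(decomp)
    return SpectraMatrix(X_star, spectra.mz, spectra.sample_ids, spectra.labels)
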