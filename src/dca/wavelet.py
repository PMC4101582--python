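"""J-level discrete wavelet transform along the m/z axis.

Each sample's spectrum is decomposed independently into detail
coefficient matrices ``cD1..cDJ`` (level 1 = finest dyadic frequency
band) and an approximation matrix ``cAJ`` holding the smooth global
shape.  With an orthogonal wavelet and periodized boundaries the
transform is orthonormal: lengths halve exactly at each level (rounding
up for odd lengths) and coefficient energy equals signal energy, which
makes the inverse transform an exact reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .io import SpectraMatrix

__all__ = ["WaveletConfig", "WaveletDecomposition", "decompose", "reconstruct"]

_MODES = {"periodization", "symmetric"}


class ConfigError(ValueError):
    """A transform configuration is infeasible for the given panel."""


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet family, decomposition depth and boundary handling.

    ``wavelet_name`` must refer to an orthogonal compact-support wavelet
    (Daubechies 'dbN', symlets, coiflets...).  ``level_J`` is the number
    of dyadic levels; under periodization it must satisfy
    ``2**level_J <= n_channels``.
    """

    wavelet_name: str = "db8"
    level_J: int = 5
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        try:
            w = pywt.Wavelet(self.wavelet_name)
        except ValueError as exc:
            raise ConfigError(f"unknown wavelet {self.wavelet_name!r}") from None
        if not w.orthogonal:
            raise ConfigError(
                f"wavelet {self.wavelet_name!r} is not orthogonal; "
                "an orthogonal compact-support wavelet is required"
            )
        if self.level_J < 1:
            raise ConfigError("level_J must be >= 1")
        if self.boundary_mode not in _MODES:
            raise ConfigError(
                f"boundary_mode must be one of {sorted(_MODES)}"
            )

    def validate_for(self, n_channels: int) -> None:
        if self.boundary_mode == "periodization":
            if 2**self.level_J > n_channels:
                raise ConfigError(
                    f"level_J={self.level_J} too deep for {n_channels} channels "
                    f"(need 2^J <= n_channels under periodization)"
                )


@dataclass
class WaveletDecomposition:
    """Ordered detail matrices ``cD1..cDJ`` plus approximation ``cAJ``.

    ``details[j-1]`` is the level-``j`` detail matrix; all matrices share
    the sample axis with the panel they came from.
    """

    details: list[np.ndarray]
    approx: np.ndarray
    config: WaveletConfig
    n_channels_original: int
    # retained so reconstructed panels keep their axis/ids/labels
    mz: np.ndarray | None = None
    sample_ids: list[str] | None = None
    labels: np.ndarray | None = None

    @property
    def level_J(self) -> int:
        return len(self.details)

    @property
    def n_samples(self) -> int:
        return self.approx.shape[0]

    def _check_shapes(self) -> None:
        n = self.approx.shape[0]
        if any(d.shape[0] != n for d in self.details):
            raise ValueError("detail/approximation matrices disagree on n_samples")

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            [d.copy() for d in self.details],
            self.approx.copy(),
            self.config,
            self.n_channels_original,
            self.mz,
            self.sample_ids,
            self.labels,
        )


def _as_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, SpectraMatrix):
        return spectra.intensities
    return np.atleast_2d(np.asarray(spectra, dtype=float))


def decompose(spectra, config: WaveletConfig) -> WaveletDecomposition:
    """J-level DWT of every sample spectrum along the m/z axis.

    Rows are transformed independently, so per-sample coefficients are
    identical to transforming that spectrum alone.
    """
    X = _as_matrix(spectra)
    config.validate_for(X.shape[1])
    with warnings.catch_warnings():
        # pywt warns when the level exceeds the filter-length heuristic;
        # periodization stays perfectly invertible at any feasible level.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(
            X,
            config.wavelet_name,
            mode=config.boundary_mode,
            level=config.level_J,
            axis=1,
        )
    # pywt order: [cA_J, cD_J, ..., cD_1] -> store details level 1..J
    approx = coeffs[0]
    details = coeffs[:0:-1]
    decomp = WaveletDecomposition(
        list(details), approx, config, X.shape[1]
    )
    if isinstance(spectra, SpectraMatrix):
        decomp.mz = spectra.mz
        decomp.sample_ids = spectra.sample_ids
        decomp.labels = spectra.labels
    return decomp


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse DWT; returns an ``n_samples x n_channels_original`` matrix.

    Linear in the coefficients.  Periodized reconstruction of an odd-length
    signal yields one surplus column, which is trimmed.
    """
    decomp._check_shapes()
    coeffs = [decomp.approx] + decomp.details[::-1]
    cfg = decomp.config
    try:
        X = pywt.waverec(
            coeffs, cfg.wavelet_name, mode=cfg.boundary_mode, axis=1
        )
    except ValueError as exc:
        raise ValueError(f"inconsistent coefficient shapes: {exc}") from None
    if X.shape[1] < decomp.n_channels_original:
        raise ValueError(
            f"coefficients reconstruct only {X.shape[1]} channels, "
            f"expected {decomp.n_channels_original}"
        )
    return X[:, : decomp.n_channels_original]
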