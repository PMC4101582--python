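"""Synthetic serum-like mass spectra with controllable class structure.

Each clean spectrum is an exponential chemical baseline plus Gaussian
peaks; classes may differ *globally* (per-class multiplicative peak
heights) and/or *subtly* (the amplitude of a fixed zero-mean
high-frequency ripple template whose energy sits in the two finest
dyadic frequency bands).  A per-sample lognormal scale factor emulates
total-ion-current variation, and independent Gaussian noise is added per
channel:

    x_s = scale_s * [ baseline + sum_p h_{g,p} Gauss_p + a_g * ripple ] + eps

The noise-free matrix (``scale_s`` times the clean spectrum) is returned
alongside so denoising can be measured against ground truth.  All
randomness flows from a single seed.

The ripple template is a fixed band-limited signal: white noise drawn
once from a dedicated generator (seed 12345), band-passed by zeroing all
wavelet coefficients outside detail levels 1 and 2 ('db8',
periodization), mixed 30% level-1 / 70% level-2 by energy, and
normalized to zero mean and unit per-channel RMS.  It is a property of
the generator, not of the simulation seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt

from .io import SpectraMatrix

__all__ = ["SimulationParams", "generate", "preset", "ripple_template"]

PRESETS = ("binary_global", "binary_subtle", "three_class")

_RIPPLE_SEED = 12345
_RIPPLE_FRAC_LEVEL1 = 0.3


@dataclass
class SimulationParams:
    """Complete description of one synthetic panel.

    ``peaks`` is a list of ``(location_mz, width_mz, base_height)``;
    ``global_effects[g][p]`` multiplies peak ``p``'s height in class
    ``g``; ``subtle_amplitude[g]`` scales the ripple template for class
    ``g``; ``baseline = (intercept, decay)`` gives
    ``intercept * exp(-decay * t)`` for ``t`` in [0, 1] across the m/z
    range.
    """

    n_per_class: tuple[int, ...] = (50, 50)
    n_channels: int = 1024
    mz_range: tuple[float, float] = (1000.0, 10000.0)
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    global_effects: list[list[float]] | None = None
    subtle_amplitude: tuple[float, ...] | None = None
    baseline: tuple[float, float] = (5.0, 3.0)
    noise_sd: float = 1.0
    sample_scale_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.n_per_class)
        if k < 1 or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class entries must be >= 1")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must be an increasing pair")
        for loc, width, height in self.peaks:
            if not lo <= loc <= hi:
                raise ValueError(f"peak location {loc} outside mz_range")
            if width <= 0:
                raise ValueError("peak widths must be positive")
        if self.global_effects is None:
            self.global_effects = [[1.0] * len(self.peaks) for _ in range(k)]
        if len(self.global_effects) != k or any(
            len(g) != len(self.peaks) for g in self.global_effects
        ):
            raise ValueError("global_effects must be k x n_peaks")
        if self.subtle_amplitude is None:
            self.subtle_amplitude = tuple(0.0 for _ in range(k))
        if len(self.subtle_amplitude) != k:
            raise ValueError("subtle_amplitude must have one entry per class")
        if self.noise_sd < 0 or self.sample_scale_sd < 0:
            raise ValueError("noise_sd and sample_scale_sd must be >= 0")

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_class))


@lru_cache(maxsize=8)
def ripple_template(n_channels: int) -> np.ndarray:
    """The fixed zero-mean, unit-RMS high-frequency template."""
    rng = np.random.default_rng(_RIPPLE_SEED)
    w = rng.standard_normal(n_channels)
    coeffs = pywt.wavedec(w, "db8", mode="periodization", level=3)
    zeros = [np.zeros_like(c) for c in coeffs]

    def band(level_from_fine: int) -> np.ndarray:
        picked = list(zeros)
        picked[-level_from_fine] = coeffs[-level_from_fine]
        r = pywt.waverec(picked, "db8", mode="periodization")[:n_channels]
        r -= r.mean()
        return r / np.sqrt(np.mean(r**2))

    r = np.sqrt(_RIPPLE_FRAC_LEVEL1) * band(1) + np.sqrt(
        1 - _RIPPLE_FRAC_LEVEL1
    ) * band(2)
    r -= r.mean()
    r /= np.sqrt(np.mean(r**2))
    r.setflags(write=False)
    return r


def _clean_class_spectra(params: SimulationParams) -> np.ndarray:
    """k x n_channels noise-free class templates."""
    mz = np.linspace(*params.mz_range, params.n_channels)
    t = (mz - params.mz_range[0]) / (params.mz_range[1] - params.mz_range[0])
    intercept, decay = params.baseline
    base = intercept * np.exp(-decay * t)
    ripple = ripple_template(params.n_channels)
    out = np.empty((params.n_classes, params.n_channels))
    for g in range(params.n_classes):
        spectrum = base.copy()
        for (loc, width, height), factor in zip(
            params.peaks, params.global_effects[g]
        ):
            spectrum += (
                height * factor * np.exp(-0.5 * ((mz - loc) / width) ** 2)
            )
        spectrum += params.subtle_amplitude[g] * ripple
        out[g] = spectrum
    return out


def generate(
    params: SimulationParams,
) -> tuple[SpectraMatrix, SpectraMatrix]:
    """Draw one panel; returns ``(noisy_panel, truth_panel)``.

    The truth panel is the per-sample scaled clean spectrum — the
    expectation of the output over the additive noise — with the same
    m/z axis, sample ids and labels.
    """
    rng = np.random.default_rng(params.seed)
    mz = np.linspace(*params.mz_range, params.n_channels)
    templates = _clean_class_spectra(params)
    n = params.n_samples
    labels = np.concatenate(
        [
            np.full(count, f"c{g + 1}")
            for g, count in enumerate(params.n_per_class)
        ]
    )
    class_idx = np.concatenate(
        [np.full(count, g) for g, count in enumerate(params.n_per_class)]
    )
    scales = (
        np.exp(rng.normal(0.0, params.sample_scale_sd, n))
        if params.sample_scale_sd > 0
        else np.ones(n)
    )
    truth = scales[:, None] * templates[class_idx]
    noise = (
        rng.normal(0.0, params.noise_sd, truth.shape)
        if params.noise_sd > 0
        else 0.0
    )
    ids = [f"s{i + 1:04d}" for i in range(n)]
    labels_arg = labels if params.n_classes >= 2 else None
    noisy = SpectraMatrix(truth + noise, mz, ids, labels_arg)
    clean = SpectraMatrix(truth, mz, ids, labels_arg)
    return noisy, clean


# Shared peak landscape for all presets: (location Da, width Da, height).
_PRESET_PEAKS = [
    (1900.0, 180.0, 40.0),
    (2980.0, 270.0, 60.0),
    (4600.0, 225.0, 30.0),
    (5950.0, 360.0, 50.0),
    (7300.0, 270.0, 25.0),
    (8650.0, 450.0, 35.0),
]


def preset(name: str, scale: float = 1.0, seed: int = 0) -> SimulationParams:
    """Documented parameter sets for the three study designs.

    ``binary_global``
        Two classes differing in the heights of two peaks (factors
        1 + 0.6*scale and 1 - 0.4*scale on peaks 2 and 4); no subtle
        effect.  Classes are disjoint on the differential peak apexes.
    ``binary_subtle``
        Identical peaks in both classes; the classes differ only in the
        ripple amplitude (1.5 -/+ 0.065*scale), far below the noise
        floor per channel.  Per-sample scale variation (lognormal
        sigma 0.2) jitters the shared ripple, so the finest detail bands
        carry a strong common variance direction aligned with the class
        difference.
    ``three_class``
        Class 2 peak heights exactly intermediate between classes 1 and
        3 (an intermediate pathological stage); no subtle effect.

    ``scale`` multiplies the differential effect (peak-height gaps, or
    the subtle amplitude difference) linearly.
    """
    if name == "binary_global":
        return SimulationParams(
            n_per_class=(50, 50),
            peaks=list(_PRESET_PEAKS),
            global_effects=[
                [1.0] * 6,
                [1.0, 1.0 + 0.6 * scale, 1.0, 1.0 - 0.4 * scale, 1.0, 1.0],
            ],
            subtle_amplitude=(0.0, 0.0),
            noise_sd=1.0,
            sample_scale_sd=0.05,
            seed=seed,
        )
    if name == "binary_subtle":
        half_gap = 0.065 * scale
        return SimulationParams(
            n_per_class=(50, 50),
            peaks=list(_PRESET_PEAKS),
            global_effects=[[1.0] * 6, [1.0] * 6],
            subtle_amplitude=(1.5 - half_gap, 1.5 + half_gap),
            noise_sd=1.0,
            sample_scale_sd=0.2,
            seed=seed,
        )
    if name == "three_class":
        delta = [0.0, 0.8 * scale, 0.0, -0.5 * scale, 0.6 * scale, 0.0]
        return SimulationParams(
            n_per_class=(40, 40, 40),
            peaks=list(_PRESET_PEAKS),
            global_effects=[
                [1.0] * 6,
                [1.0 + d / 2 for d in delta],
                [1.0 + d for d in delta],
            ],
            subtle_amplitude=(0.0, 0.0, 0.0),
            noise_sd=1.0,
            sample_scale_sd=0.05,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
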