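import numpy as np
import pytest

from dca import (
    DCAConfig,
    EigenSpectrum,
    WaveletConfig,
    apply_model,
    decompose,
    fit_transform,
    rank_reduce_detail,
    variability_ratio,
)
from dca.simulate import SimulationParams, generate
from dca.wavelet import ConfigError

from conftest import make_panel


class TestVariabilityRatio:
    def test_direct_arithmetic(self):
        assert variability_ratio(EigenSpectrum([3.0, 1.0]), 1) == 0.75

    def test_full_sum_is_one(self, rng):
        v = np.sort(rng.exponential(size=7))[::-1]
        assert variability_ratio(EigenSpectrum(v), 7) == pytest.approx(1.0)

    def test_equal_eigenvalues(self):
        assert variability_ratio(EigenSpectrum([1.0] * 4), 1) == 0.25

    def test_degenerate_zero_spectrum_warns(self):
        with pytest.warns(UserWarning, match="zero total"):
            assert variability_ratio(EigenSpectrum([0.0, 0.0]), 1) == 1.0

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            variability_ratio(EigenSpectrum([1.0]), 2)


class TestRankReduce:
    def test_full_rank_is_identity(self, rng):
        D = rng.normal(size=(6, 4))
        reduced, _ = rank_reduce_detail(D, 4)
        np.testing.assert_allclose(reduced, D, atol=1e-8)

    def test_exact_rank_one_input(self, rng):
        D = np.outer(rng.normal(size=8), rng.normal(size=5))
        D -= D.mean(axis=0)
        reduced, _ = rank_reduce_detail(D, 1)
        np.testing.assert_allclose(reduced, D, atol=1e-8)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_eckart_young_oracle(self, m):
        """Output equals mean + rank-m SVD truncation of the centered matrix."""
        for seed in range(20):
            D = np.random.default_rng(seed).normal(size=(20, 64))
            mean = D.mean(axis=0)
            U, s, Vt = np.linalg.svd(D - mean, full_matrices=False)
            expected = (U[:, :m] * s[:m]) @ Vt[:m] + mean
            reduced, model = rank_reduce_detail(D, m)
            np.testing.assert_allclose(reduced, expected, atol=1e-10)
            assert model.loadings.shape == (64, m)

    def test_loadings_orthonormal(self, rng):
        _, model = rank_reduce_detail(rng.normal(size=(10, 30)), 3)
        G = model.loadings.T @ model.loadings
        np.testing.assert_allclose(G, np.eye(3), atol=1e-8)

    def test_m_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_reduce_detail(rng.normal(size=(5, 8)), 6)


class TestFitTransform:
    def test_identity_when_tau_zero(self):
        panel = make_panel(10, 1024, seed=5)
        cfg = DCAConfig(wavelet=WaveletConfig("db8", 5), cutoff_tau=0)
        meta, model = fit_transform(panel, cfg)
        np.testing.assert_allclose(
            meta.intensities, panel.intensities, atol=1e-8
        )
        assert model.levels == {}

    def test_identity_limit_full_m(self):
        """Full-rank reconstruction of every fine level is the identity."""
        panel = make_panel(10, 1024, seed=5)
        cfg = DCAConfig(
            wavelet=WaveletConfig("db8", 5), cutoff_tau=2, n_components=10
        )
        meta, _ = fit_transform(panel, cfg)
        err = np.linalg.norm(meta.intensities - panel.intensities)
        assert err / np.linalg.norm(panel.intensities) <= 1e-8

    def test_default_shapes_and_ratios(self):
        panel = make_panel(10, 1024, seed=5)
        meta, model = fit_transform(panel, DCAConfig())
        assert meta.intensities.shape == (10, 1024)
        assert sorted(model.levels) == [1, 2]
        for level in model.levels.values():
            assert 0.0 <= level.explained_ratio <= 1.0

    def test_coarse_levels_intact(self):
        """Only levels <= tau change; the rest pass through the inverse."""
        panel = make_panel(12, 512, seed=9)
        cfg = DCAConfig(wavelet=WaveletConfig("db8", 5), cutoff_tau=2)
        meta, _ = fit_transform(panel, cfg)
        before = decompose(panel, cfg.wavelet)
        after = decompose(meta, cfg.wavelet)
        for j in range(3, 6):
            np.testing.assert_allclose(
                after.details[j - 1], before.details[j - 1], atol=1e-9
            )
        np.testing.assert_allclose(after.approx, before.approx, atol=1e-9)

    def test_monotone_fidelity(self):
        """More retained components bring meta-data closer to the input."""
        panel = make_panel(15, 256, seed=2)
        dists = []
        for m in (1, 2, 3, 5):
            cfg = DCAConfig(
                wavelet=WaveletConfig("db8", 4), cutoff_tau=2, n_components=m
            )
            meta, _ = fit_transform(panel, cfg)
            dists.append(np.linalg.norm(meta.intensities - panel.intensities))
        assert all(a >= b - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_noise_suppression_on_simulation(self):
        """Meta-data lies closer to the noise-free truth than the raw panel."""
        params = SimulationParams(
            n_per_class=(20, 20),
            peaks=[(3000.0, 250.0, 50.0), (6000.0, 400.0, 30.0)],
            noise_sd=1.0,
            seed=42,
        )
        noisy, truth = generate(params)
        meta, _ = fit_transform(noisy, DCAConfig())
        d_meta = np.linalg.norm(meta.intensities - truth.intensities)
        d_raw = np.linalg.norm(noisy.intensities - truth.intensities)
        assert d_meta < d_raw

    def test_rho_threshold_mode_runs(self):
        panel = make_panel(10, 256, seed=1)
        cfg = DCAConfig(
            wavelet=WaveletConfig("db8", 4),
            cutoff_tau=2,
            ratio_threshold=0.6,
        )
        meta, model = fit_transform(panel, cfg)
        for level in model.levels.values():
            assert level.explained_ratio >= 0.6 or level.m == 10

    def test_invalid_tau_rejected(self):
        with pytest.raises(ConfigError):
            DCAConfig(wavelet=WaveletConfig("db8", 4), cutoff_tau=5)

    def test_out_of_recommended_range_warns(self):
        panel = make_panel(6, 256, seed=1)
        cfg = DCAConfig(wavelet=WaveletConfig("db8", 3), cutoff_tau=3)
        with pytest.warns(UserWarning):
            fit_transform(panel, cfg)


class TestApplyModel:
    def test_self_consistency(self):
        panel = make_panel(10, 512, seed=7)
        cfg = DCAConfig(wavelet=WaveletConfig("db8", 5))
        meta, model = fit_transform(panel, cfg)
        reapplied = apply_model(model, panel)
        np.testing.assert_allclose(
            reapplied.intensities, meta.intensities, atol=1e-8
        )

    def test_projection_residual_oracle(self):
        """Projection matches direct (coeffs-mean) - UU'(coeffs-mean)."""
        panel = make_panel(10, 512, seed=7)
        cfg = DCAConfig(wavelet=WaveletConfig("db8", 5))
        _, model = fit_transform(panel, cfg)
        new = make_panel(3, 512, seed=99)
        projected = apply_model(model, new)
        dec_new = decompose(new, cfg.wavelet)
        dec_proj = decompose(projected, cfg.wavelet)
        for j, level in model.levels.items():
            U = level.loadings
            centered = dec_new.details[j - 1] - level.mean_vector
            expected = centered @ U @ U.T + level.mean_vector
            np.testing.assert_allclose(
                dec_proj.details[j - 1], expected, atol=1e-10
            )

    def test_channel_mismatch_rejected(self):
        panel = make_panel(10, 512, seed=7)
        _, model = fit_transform(
            panel, DCAConfig(wavelet=WaveletConfig("db8", 5))
        )
        with pytest.raises(ValueError, match="channel"):
            apply_model(model, make_panel(2, 256, seed=0))
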