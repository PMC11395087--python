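"""Synthetic-scene generator: contracts, determinism and recoverability."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from ginkgoflav import envi
from ginkgoflav.calibration import calibrate_cube
from ginkgoflav.simulate import (
    SimulationConfig,
    background_spectrum,
    dataset_truth,
    generate_dataset,
    iter_scenes,
    leaf_reflectance_spectrum,
    make_wavelength_grid,
    render_leaf_mask,
    render_raw_scene,
    sample_tfc_values,
    truth_csv_bytes,
)


class TestWavelengthGrid:
    @pytest.mark.parametrize(
        "n,start,end,expected",
        [
            (2, 381.8, 1020.5, [381.8, 1020.5]),
            (3, 0.0, 10.0, [0.0, 5.0, 10.0]),
        ],
    )
    def test_endpoints_and_spacing(self, n, start, end, expected):
        np.testing.assert_allclose(
            make_wavelength_grid(n, start, end), expected)

    def test_native_range_step(self):
        grid = make_wavelength_grid(100, 381.8, 1020.5)
        steps = np.diff(grid)
        np.testing.assert_allclose(steps, (1020.5 - 381.8) / 99, rtol=1e-12)
        assert grid[0] == 381.8 and grid[-1] == 1020.5

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError):
            make_wavelength_grid(1, 400.0, 700.0)
        with pytest.raises(ValueError):
            make_wavelength_grid(5, 700.0, 400.0)


class TestTfcSampling:
    def test_default_counts(self):
        cfg = SimulationConfig()
        pairs = sample_tfc_values(cfg, np.random.default_rng(0))
        assert len(pairs) == 407
        assert sum(p == "LL" for p, _ in pairs) == 207
        assert sum(p == "UL" for p, _ in pairs) == 200
        vals = np.array([v for _, v in pairs])
        assert vals.min() >= cfg.tfc_min and vals.max() <= cfg.tfc_max

    def test_zero_shift_symmetric(self):
        cfg = SimulationConfig(n_lobed=2000, n_unlobed=2000,
                               lobed_tfc_shift=0.0)
        pairs = sample_tfc_values(cfg, np.random.default_rng(1))
        ll = np.array([v for p, v in pairs if p == "LL"])
        ul = np.array([v for p, v in pairs if p == "UL"])
        se = np.sqrt(ll.var(ddof=1) / ll.size + ul.var(ddof=1) / ul.size)
        assert abs(ll.mean() - ul.mean()) < 2 * se

    def test_shift_recovered_at_large_n(self):
        cfg = SimulationConfig(n_lobed=10000, n_unlobed=10000,
                               lobed_tfc_shift=2.0)
        pairs = sample_tfc_values(cfg, np.random.default_rng(2))
        ll = np.mean([v for p, v in pairs if p == "LL"])
        ul = np.mean([v for p, v in pairs if p == "UL"])
        assert ll - ul == pytest.approx(2.0, abs=0.1)

    def test_bulk_of_mass_in_mode_interval(self):
        cfg = SimulationConfig(n_lobed=3000, n_unlobed=3000)
        vals = np.array(
            [v for _, v in sample_tfc_values(cfg, np.random.default_rng(3))])
        width = cfg.tfc_mode_high - cfg.tfc_mode_low
        center = np.mean((vals >= cfg.tfc_mode_low)
                         & (vals <= cfg.tfc_mode_high))
        below = np.mean((vals >= cfg.tfc_mode_low - width)
                        & (vals < cfg.tfc_mode_low))
        above = np.mean((vals > cfg.tfc_mode_high)
                        & (vals <= cfg.tfc_mode_high + width))
        assert center > below and center > above


class TestLeafSpectrum:
    def test_seeded_determinism(self):
        wl = make_wavelength_grid(80, 381.8, 1020.5)
        a = leaf_reflectance_spectrum(
            12.0, wl, np.random.default_rng(5), noise_sd=0.01)
        b = leaf_reflectance_spectrum(
            12.0, wl, np.random.default_rng(5), noise_sd=0.01)
        np.testing.assert_array_equal(a, b)

    def test_reflectance_in_open_unit_interval(self):
        wl = make_wavelength_grid(200, 381.8, 1020.5)
        for tfc in (6.2, 13.5, 20.5):
            spec = leaf_reflectance_spectrum(tfc, wl)
            assert np.all(spec > 0) and np.all(spec < 1)

    def test_tfc_moves_only_the_signal_window(self):
        cfg = SimulationConfig()
        wl = cfg.wavelengths
        lo = leaf_reflectance_spectrum(6.2, wl, config=cfg)
        hi = leaf_reflectance_spectrum(20.5, wl, config=cfg)
        diff = hi - lo
        # the affine link: difference = gain * dtfc * normalized weights
        win = (wl >= cfg.signal_window[0]) & (wl <= cfg.signal_window[1])
        expected_window_mean = cfg.signal_gain * (20.5 - 6.2)
        assert diff[win].mean() == pytest.approx(expected_window_mean,
                                                 rel=1e-9)
        far = (wl > 750.0)  # weights decay to ~0 away from the window
        assert np.max(np.abs(diff[far])) < 1e-6

    def test_ols_recovers_configured_gain(self):
        cfg = SimulationConfig(n_lobed=200, n_unlobed=200,
                               sensor_noise_sd=0.0, n_gross_outliers=0)
        wl = cfg.wavelengths
        win = (wl >= cfg.signal_window[0]) & (wl <= cfg.signal_window[1])
        tfc = np.linspace(cfg.tfc_min + 0.1, cfg.tfc_max - 0.1, 50)
        amp = np.array([
            leaf_reflectance_spectrum(t, wl, config=cfg)[win].mean()
            for t in tfc])
        slope = np.polyfit(tfc, amp, 1)[0]
        assert slope == pytest.approx(cfg.signal_gain, abs=1e-6)

    def test_red_edge_and_chlorophyll_plateau(self):
        wl = make_wavelength_grid(300, 381.8, 1020.5)
        spec = leaf_reflectance_spectrum(13.0, wl)
        nir = spec[(wl > 760) & (wl < 900)].mean()
        visible = spec[(wl > 500) & (wl < 700)].mean()
        assert nir > 2 * visible  # steep red-edge rise
        # water-related dip near 970 nm relative to the NIR shoulder
        assert spec[np.argmin(np.abs(wl - 970))] < spec[
            np.argmin(np.abs(wl - 870))]


class TestLeafMask:
    @pytest.mark.parametrize("lobed", [False, True])
    def test_connected_with_sane_coverage(self, lobed):
        for seed in range(5):
            mask = render_leaf_mask(64, 64, lobed,
                                    np.random.default_rng(seed))
            _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n_comp == 1
            assert 0.10 <= mask.mean() <= 0.60

    def test_lobed_leaves_have_clefts(self):
        # a cleft makes the lobed silhouette a strict subset of the margin
        lobe = render_leaf_mask(64, 64, True, np.random.default_rng(11))
        plain = render_leaf_mask(64, 64, False, np.random.default_rng(11))
        assert lobe.sum() < plain.sum()

    def test_seeded_determinism(self):
        a = render_leaf_mask(48, 48, True, np.random.default_rng(9))
        b = render_leaf_mask(48, 48, True, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            render_leaf_mask(8, 64, False, np.random.default_rng(0))


class TestRenderScene:
    def _scene(self, noise_sd, seed=21):
        cfg = SimulationConfig(image_height=32, image_width=32, n_bands=50,
                               sensor_noise_sd=noise_sd)
        wl = cfg.wavelengths
        rng = np.random.default_rng(seed)
        mask = render_leaf_mask(32, 32, False, rng)
        leaf = leaf_reflectance_spectrum(13.0, wl, config=cfg)
        bg = background_spectrum(wl)
        raw, white, dark = render_raw_scene(mask, leaf, bg, cfg, rng)
        refl = np.where(mask[:, :, None], leaf[None, None, :],
                        bg[None, None, :])
        return raw, white, dark, refl, mask, leaf, bg

    def test_zero_noise_roundtrip_is_exact(self):
        raw, white, dark, refl, *_ = self._scene(0.0)
        recovered = calibrate_cube(raw, white, dark)
        assert np.max(np.abs(recovered - refl)) < 1e-12

    def test_leaf_background_contrast_is_affine(self):
        raw, white, dark, _, mask, leaf, bg = self._scene(0.0)
        iy, ix = np.argwhere(mask)[0]
        oy, ox = np.argwhere(~mask)[0]
        expected = (leaf - bg) * (white[iy, ix] - dark[iy, ix])
        # same-pixel references: compare against the leaf pixel's frames
        observed = (raw[iy, ix] - dark[iy, ix]) - \
            (bg * (white[iy, ix] - dark[iy, ix]))
        np.testing.assert_allclose(observed, expected, atol=1e-12)
        assert np.all(raw[iy, ix] != raw[oy, ox])

    def test_noise_tail_bound(self):
        # ~unit white-dark denominator: max abs error over ~1e4 values
        # stays within 5 noise sd (Gaussian tail at this sample size)
        cfg = SimulationConfig(image_height=16, image_width=16, n_bands=100,
                               sensor_noise_sd=0.01)
        rng = np.random.default_rng(33)
        mask = render_leaf_mask(16, 16, False, rng)
        leaf = leaf_reflectance_spectrum(13.0, cfg.wavelengths, config=cfg)
        bg = background_spectrum(cfg.wavelengths)
        raw, white, dark = render_raw_scene(mask, leaf, bg, cfg, rng)
        refl = np.where(mask[:, :, None], leaf[None, None, :],
                        bg[None, None, :])
        err = np.abs(calibrate_cube(raw, white, dark) - refl)
        assert err.max() <= 5 * 0.01

    def test_background_must_be_darker(self):
        cfg = SimulationConfig(image_height=32, image_width=32, n_bands=50)
        rng = np.random.default_rng(2)
        mask = render_leaf_mask(32, 32, False, rng)
        leaf = leaf_reflectance_spectrum(13.0, cfg.wavelengths, config=cfg)
        with pytest.raises(ValueError, match="darker"):
            render_raw_scene(mask, leaf, leaf + 0.2, cfg, rng)


class TestDataset:
    def test_default_truth_counts(self):
        truth = dataset_truth(SimulationConfig())
        assert len(truth) == 407
        assert (truth.phenotype == "LL").sum() == 207
        assert (truth.phenotype == "UL").sum() == 200
        assert truth.is_injected_outlier.sum() == 20

    def test_no_outliers_means_no_flags(self, small_config):
        truth = dataset_truth(small_config)
        assert not truth.is_injected_outlier.any()

    def test_truth_table_bytes_deterministic(self, small_config):
        a = truth_csv_bytes(dataset_truth(small_config))
        b = truth_csv_bytes(dataset_truth(small_config))
        assert a == b

    def test_scene_stream_matches_truth(self, small_config):
        truth = dataset_truth(small_config)
        ids = [s.sample_id for s in iter_scenes(small_config)]
        assert ids == list(truth.sample_id)

    def test_envi_export_roundtrip(self, small_config, tmp_path):
        cfg = dataclasses.replace(small_config, n_lobed=1, n_unlobed=1)
        scenes, truth = generate_dataset(cfg, tmp_path)
        assert (tmp_path / "truth.csv").exists()
        cube, wl = envi.read_envi(tmp_path / scenes[0].sample_id)
        np.testing.assert_allclose(cube, scenes[0].raw, atol=1e-6)
        np.testing.assert_allclose(wl, scenes[0].wavelengths, atol=1e-4)
        on_disk = pd.read_csv(tmp_path / "truth.csv")
        assert list(on_disk.sample_id) == list(truth.sample_id)

    def test_spectra_table_shape(self, small_table, small_config):
        assert len(small_table) == small_config.n_samples
        band_cols = [c for c in small_table.columns
                     if c not in ("sample_id", "phenotype", "tfc",
                                  "is_injected_outlier")]
        assert len(band_cols) == small_config.n_bands

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_lobed=0)
        with pytest.raises(ValueError):
            SimulationConfig(wavelength_start=1000.0, wavelength_end=400.0)
        with pytest.raises(ValueError):
            SimulationConfig(tfc_min=13.0, tfc_mode_low=12.0)
        with pytest.raises(ValueError):
            SimulationConfig(sensor_noise_sd=-0.1)
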