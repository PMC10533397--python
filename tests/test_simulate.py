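"""Synthetic FOV generator: determinism, forward-model identities, truth."""

import math

import numpy as np
import pytest

from traqg import (
    DEFAULT_SENSOR,
    FOVConfig,
    generate_blank,
    generate_fov,
    generate_timelapse,
    generate_titration,
    fit_titration,
    preset_config,
    ratio_response,
)
from traqg.simulate import FLAT_PROFILE, NUCLEUS_CYCLE_PROFILE, TimelapseProfile


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config):
        p1, l1, t1 = generate_fov(small_config)
        p2, l2, t2 = generate_fov(small_config)
        assert np.array_equal(p1.fp, p2.fp) and np.array_equal(p1.sir, p2.sir)
        assert np.array_equal(l1, l2)
        assert t1.cells.equals(t2.cells)

    def test_different_seed_differs(self, small_config):
        p1, _, _ = generate_fov(small_config)
        p2, _, _ = generate_fov(small_config.replace(seed=small_config.seed + 1))
        assert not np.array_equal(p1.fp, p2.fp)


class TestForwardModelIdentities:
    def test_noiseless_ratio_identity(self, clean_config):
        """With noise off and uniform GSH, fp/sir inside every cell equals
        r0*(1+g/kd) pixel-for-pixel."""
        pair, labels, truth = generate_fov(clean_config)
        expected = ratio_response(clean_config.gsh_mean_mM, DEFAULT_SENSOR)
        inside = labels > 0
        ratios = pair.fp[inside] / pair.sir[inside]
        assert np.all(np.abs(ratios - expected) < 1e-9)

    def test_flux_conservation(self, clean_config):
        """Total noiseless FP flux = background*Npix + sum over cells of
        expression * brightness * area."""
        cfg = clean_config.replace(background_fp=7.0, background_sir=3.0)
        _, labels, truth = generate_fov(cfg)
        npix = cfg.height_px * cfg.width_px
        total = cfg.background_fp * npix
        for _, row in truth.cells.iterrows():
            area = int((labels == row.label).sum())
            total += row.expression * DEFAULT_SENSOR.brightness_fp * area
        assert truth.expected_fp.sum() == pytest.approx(total, rel=1e-6)

    def test_truth_ratio_independent_of_expression(self, clean_config):
        """Scaling the expression distribution leaves the true ratio field
        untouched (ratio cancels expression)."""
        _, _, t1 = generate_fov(clean_config)
        _, _, t2 = generate_fov(clean_config.replace(expression_median=2.0))
        assert np.allclose(t1.cells.true_ratio, t2.cells.true_ratio)
        assert np.allclose(t2.cells.expression, 2.0 * t1.cells.expression)

    def test_labels_inside_recorded_ellipses(self, small_config):
        _, labels, truth = generate_fov(small_config)
        for _, row in truth.cells.iterrows():
            rr, cc = np.nonzero(labels == row.label)
            dr, dc = rr - row.row, cc - row.col
            u = dr * math.cos(row.theta_rad) + dc * math.sin(row.theta_rad)
            v = -dr * math.sin(row.theta_rad) + dc * math.cos(row.theta_rad)
            assert np.all((u / row.semi_a) ** 2 + (v / row.semi_b) ** 2 <= 1.0 + 1e-9)

    def test_labels_contiguous_and_nonempty(self, small_config):
        _, labels, truth = generate_fov(small_config)
        ids = sorted(truth.cells.label)
        assert ids == list(range(1, truth.n_placed + 1))
        for lab in ids:
            assert (labels == lab).sum() > 0


class TestBackgroundAndBlanks:
    def test_empty_fov_mean_near_background(self):
        cfg = FOVConfig(n_cells=0, background_fp=50.0, read_noise_sd=0.0, seed=7)
        pair, labels, _ = generate_fov(cfg)
        assert labels.max() == 0
        npix = cfg.height_px * cfg.width_px
        se = math.sqrt(cfg.background_fp / npix)
        assert abs(pair.fp.mean() - cfg.background_fp) < 3 * se

    def test_zero_background_zero_image(self):
        cfg = FOVConfig(
            n_cells=0, background_fp=0.0, background_sir=0.0,
            read_noise_sd=0.0, shot_noise=False, seed=1,
        )
        blank = generate_blank(cfg)
        assert np.all(blank.fp == 0.0) and np.all(blank.sir == 0.0)

    def test_large_exposure_blank_converges(self):
        """Law of large numbers: with many photons the sample mean is
        within 0.5% of the background."""
        cfg = FOVConfig(
            height_px=512, width_px=512, n_cells=0,
            background_fp=500.0, background_sir=500.0, read_noise_sd=0.0, seed=2,
        )
        blank = generate_blank(cfg)
        assert abs(blank.fp.mean() - 500.0) / 500.0 < 0.005

    def test_independent_noise_between_seeds(self):
        cfg = FOVConfig(n_cells=0, background_fp=80.0, seed=1)
        b1 = generate_blank(cfg)
        b2 = generate_blank(cfg.replace(seed=2))
        r = np.corrcoef(b1.fp.ravel(), b2.fp.ravel())[0, 1]
        assert abs(r) < 0.05


class TestPackingAndConfig:
    def test_infeasible_packing_warns(self):
        cfg = FOVConfig(height_px=96, width_px=96, n_cells=50, border_margin_px=8,
                        radius_px_range=(10.0, 14.0), seed=0)
        _, _, truth = generate_fov(cfg)
        assert truth.n_placed < truth.n_requested
        assert truth.warnings

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FOVConfig(height_px=32)
        with pytest.raises(ValueError):
            FOVConfig(radius_px_range=(0.0, 5.0))
        with pytest.raises(KeyError):
            preset_config("golgi")

    def test_presets_set_distribution(self):
        cfg = preset_config("whole_cell")
        assert (cfg.gsh_mean_mM, cfg.gsh_sd_mM) == (18.9, 9.4)

    def test_lognormal_gsh_moments(self):
        cfg = FOVConfig(
            height_px=512, width_px=512, n_cells=40, gsh_dist="lognormal",
            gsh_mean_mM=14.0, gsh_sd_mM=6.7, radius_px_range=(5.0, 8.0), seed=4,
        )
        _, _, truth = generate_fov(cfg)
        g = truth.cells.gsh_mM
        assert np.all(g > 0)
        assert abs(g.mean() - 14.0) < 4 * 6.7 / math.sqrt(len(g))


class TestTwoCompartmentMode:
    def test_nuclear_offset_changes_inner_sir(self, clean_config):
        cfg = clean_config.replace(nucleus_fraction=0.25, nucleus_gsh_offset_mM=6.0)
        pair, labels, truth = generate_fov(cfg)
        assert "gsh_nuc_mM" in truth.cells.columns
        row = truth.cells.iloc[0]
        inside = labels == row.label
        ratios = pair.fp[inside] / pair.sir[inside]
        outer = ratio_response(row.gsh_mM, DEFAULT_SENSOR)
        inner = ratio_response(row.gsh_nuc_mM, DEFAULT_SENSOR)
        # both compartment ratios present within the one cell
        assert np.isclose(ratios.max(), inner, atol=1e-9)
        assert np.isclose(ratios.min(), outer, atol=1e-9)


class TestTimelapse:
    def test_frame_grid(self):
        frames = list(generate_timelapse(
            FOVConfig(n_cells=3, seed=5), NUCLEUS_CYCLE_PROFILE, drift_sd_px=0.0,
        ))
        assert len(frames) == 49
        times = [t for t, *_ in frames]
        assert times[0] == 0.0 and times[-1] == pytest.approx(24.0)
        assert np.allclose(np.diff(times), 0.5)

    def test_declining_profile_truth_matches_exactly(self):
        """With zero per-cell scatter the ground-truth mean at each frame
        equals the interpolated profile."""
        profile = TimelapseProfile(
            breakpoints=((0.0, 14.0), (12.0, 7.0)), n_frames=25, cell_sd_mM=0.0,
        )
        cfg = FOVConfig(n_cells=4, seed=8)
        for t, _, _, truth in generate_timelapse(cfg, profile, drift_sd_px=0.0):
            assert truth.cells.gsh_mM.mean() == pytest.approx(
                float(profile.mean_at(t)), abs=1e-12
            )

    def test_cells_persist_and_drift(self):
        cfg = FOVConfig(n_cells=5, seed=9)
        frames = list(generate_timelapse(cfg, FLAT_PROFILE, drift_sd_px=2.0))
        n0 = frames[0][3].n_placed
        for _, _, _, truth in frames:
            assert truth.n_placed == n0
        c0 = frames[0][3].cells[["row", "col"]].to_numpy()
        c1 = frames[-1][3].cells[["row", "col"]].to_numpy()
        assert not np.allclose(c0, c1)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            TimelapseProfile(breakpoints=((0.0, 5.0),))
        with pytest.raises(ValueError):
            TimelapseProfile(breakpoints=((0.0, 5.0), (0.0, 6.0)))


class TestTitrationGeneration:
    def test_zero_noise_is_exact_model(self, sensor):
        concs = np.linspace(0, 40, 9)
        s = generate_titration(sensor, concs, noise_cv=0.0, offset=20.0)
        expected = sensor.brightness_sir0 / (1 + concs / sensor.kd_mM) + 20.0
        assert np.allclose(s.responses, expected)
        assert np.all(np.asarray(s.replicate_sd) == 0.0)

    def test_single_zero_concentration(self, sensor):
        s = generate_titration(sensor, [0.0], noise_cv=0.0, offset=20.0)
        assert s.responses[0] == pytest.approx(sensor.brightness_sir0 + 20.0)

    def test_round_trip_recovers_kd(self, sensor):
        """Generate-then-fit at 2% noise: mean fitted kd over replicates
        within 5% of truth (a single fit scatters ~5% itself)."""
        kds = [
            fit_titration(
                generate_titration(
                    sensor, np.linspace(0.5, 40, 12), noise_cv=0.02,
                    seed=70 + rep, offset=20.0,
                ),
                model="turnoff",
            ).kd_mM
            for rep in range(40)
        ]
        assert abs(np.mean(kds) - sensor.kd_mM) / sensor.kd_mM < 0.05
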