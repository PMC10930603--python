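"""Generator ground-truth guarantees: determinism, static limits,
controlled turnover, effect injection, and image/mask consistency."""

import numpy as np
import pytest

from cerequant.dynamics import motility_index
from cerequant.synthgen import (
    AMPLITUDE,
    SynthConfig,
    generate_fixed_section,
    generate_injury_series,
    generate_timelapse,
    generate_volume_region,
)


class TestTimelapse:
    def test_static_limit_masks_identical(self, clean_invivo_config):
        cfg = clean_invivo_config.replace(process_turnover=0.0)
        _, truth = generate_timelapse(cfg)
        for t in range(1, cfg.n_timepoints):
            assert np.array_equal(truth.microglia_masks[t], truth.microglia_masks[0])

    def test_zero_bleed_leaves_microglia_channel_pure(self, clean_invivo_config):
        stack, truth = generate_timelapse(clean_invivo_config)
        mic = stack.data[:, :, 0]
        # every nonzero voxel of the microglia channel is a microglia voxel
        assert np.array_equal(mic > 0, truth.microglia_masks)

    @pytest.mark.parametrize("m", [0.05, 0.1])
    def test_turnover_controls_motility_index(self, clean_invivo_config, m):
        cfg = clean_invivo_config.replace(process_turnover=m, seed=7)
        _, truth = generate_timelapse(cfg)
        for layer in ("ML", "PCL"):
            masks = [
                truth.layer_projection(layer, t) for t in range(cfg.n_timepoints)
            ]
            res = motility_index(masks)
            assert res.motility_index == pytest.approx(m, abs=0.02)

    def test_bit_exact_determinism(self, small_invivo_config):
        s1, t1 = generate_timelapse(small_invivo_config)
        s2, t2 = generate_timelapse(small_invivo_config)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.microglia_masks, t2.microglia_masks)
        assert np.array_equal(t1.drift_offsets, t2.drift_offsets)

    def test_threshold_at_emission_recovers_mask(self, clean_invivo_config):
        cfg = clean_invivo_config.replace(bleed_alpha=0.2)
        stack, truth = generate_timelapse(cfg)
        assert np.array_equal(stack.data[:, :, 0] >= AMPLITUDE, truth.microglia_masks)
        assert np.array_equal(
            stack.data[0, :, 1] >= AMPLITUDE, truth.purkinje_mask
        )

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SynthConfig(image_shape=(8, 128))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(bleed_alpha=1.0)
        with pytest.raises(ValueError):
            SynthConfig(process_turnover=1.5)


class TestFixedSection:
    def test_layer_rois_partition_and_are_valid(self):
        cfg = SynthConfig(image_shape=(128, 128), fixed_n_slices=6, seed=0)
        _, rois, _ = generate_fixed_section(cfg)
        assert set(rois) == {"ML+PCL", "GL", "WM"}
        total = sum(r.area_um2 for r in rois.values())
        ny, nx = cfg.image_shape
        assert total == pytest.approx((ny - 1) * (nx - 1), rel=0.02)
        for roi in rois.values():
            assert roi.shapely.is_valid

    def test_pcl_soma_count_matches_spacing(self):
        # ~1040 um path at 100 um spacing -> about 10 somas
        cfg = SynthConfig(
            image_shape=(128, 1024), fixed_n_slices=6, pcl_soma_spacing_um=100.0,
            noise_sd=0.0, seed=5,
        )
        _, _, truth = generate_fixed_section(cfg)
        expected = truth.params["pcl_length_um"] / 100.0
        assert len(truth.purkinje_somas) == pytest.approx(expected, abs=2)

    def test_group_effect_scales_intended_linear_frequency_exactly(self):
        base = SynthConfig(image_shape=(128, 256), fixed_n_slices=6, seed=3)
        eff = base.replace(
            treatment="ethanol",
            group_effects={"ethanol": {"pcl_linear_density": 0.5}},
        )
        assert eff.effect("pcl_linear_density") == 0.5
        _, _, t0 = generate_fixed_section(base)
        _, _, t1 = generate_fixed_section(eff)
        ratio = (
            t1.params["intended_linear_frequency"]
            / t0.params["intended_linear_frequency"]
        )
        assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_microglia_count_tracks_density(self):
        dens = 3e-4
        cfg = SynthConfig(
            image_shape=(256, 256), fixed_n_slices=6, placement="poisson",
            microglia_density_per_layer={"ML+PCL": dens, "GL": dens, "WM": dens},
            microglia_arbors=False, seed=9,
        )
        _, rois, truth = generate_fixed_section(cfg)
        for label, roi in rois.items():
            n = len(truth.microglia_somas[label])
            lam = dens * roi.area_um2
            assert abs(n - lam) <= 3 * np.sqrt(lam) + 1  # Poisson error

    def test_deterministic(self):
        cfg = SynthConfig(image_shape=(96, 96), fixed_n_slices=6, seed=11)
        s1, _, _ = generate_fixed_section(cfg)
        s2, _, _ = generate_fixed_section(cfg)
        assert np.array_equal(s1.data, s2.data)


class TestInjurySeries:
    def test_zero_rate_keeps_proximity_at_one(self):
        cfg = SynthConfig(image_shape=(96, 96), injury_rate_px=0.0, noise_sd=0, seed=1)
        _, truth = generate_injury_series(cfg)
        assert np.allclose(truth.proximity, 1.0)

    def test_analytic_circle_area_series(self):
        cfg = SynthConfig(
            image_shape=(128, 128), injury_core_radius_px=10,
            injury_front_radius_px=30, injury_rate_px=2.0, noise_sd=0, seed=1,
        )
        _, truth = generate_injury_series(cfg)
        radii = np.maximum(10, 30 - 2.0 * np.arange(cfg.n_timepoints))
        expected = (radii**2 - 100) / (900 - 100)
        assert np.allclose(truth.proximity, expected)

    def test_fast_front_reaches_core(self):
        cfg = SynthConfig(
            image_shape=(128, 128), injury_core_radius_px=10,
            injury_front_radius_px=40, injury_rate_px=6.0, noise_sd=0, seed=1,
        )
        _, truth = generate_injury_series(cfg)
        assert np.all(truth.proximity[6:] == 0.0)
        assert np.all(np.diff(truth.proximity) <= 1e-12)

    def test_core_outside_field_rejected(self):
        cfg = SynthConfig(image_shape=(64, 64), injury_core_radius_px=40)
        with pytest.raises(ValueError, match="inside the field"):
            generate_injury_series(cfg)


class TestVolumeRegion:
    def test_occupancy_is_exact_in_voxel_count(self):
        cfg = SynthConfig(seed=2, noise_sd=0.0)
        shape = (12, 64, 64)
        section, truth = generate_volume_region(cfg, 0.01, shape=shape)
        target = round(0.01 * np.prod(shape))
        assert truth.params["n_voxels"] == target
        assert int((section.data[:, 0] > 0).sum()) == target

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            generate_volume_region(SynthConfig(), 1.5, shape=(4, 32, 32))
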