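"""Preprocessing: blinding, drift recovery, bleed-through estimation and
subtraction, temporal PCA denoising, and layer splitting."""

import numpy as np
import pytest

from cerequant.containers import TimelapseStack
from cerequant.preprocess import (
    blind_dataset,
    correct_drift,
    estimate_bleedthrough,
    max_project,
    pca_denoise,
    split_layers,
    subtract_bleedthrough,
)
from cerequant.synthgen import generate_timelapse


def _purkinje_only(truth):
    return truth.purkinje_mask & ~truth.microglia_masks.any(axis=0)


class TestBlinding:
    def test_bijection_and_determinism(self):
        paths = [f"stack_{i}.tiff" for i in range(4)]
        m1, key = blind_dataset(paths, seed=7)
        m2, _ = blind_dataset(paths, seed=7)
        assert m1 == m2
        assert len(set(m1.values())) == 4

    def test_key_table_round_trips_names(self):
        paths = ["a.tiff", "b.tiff", "c.tiff"]
        mapping, key = blind_dataset(paths, seed=1)
        recovered = dict(zip(key["blinded_id"], key["original_path"]))
        assert {recovered[v]: v for v in mapping.values()} == {
            p: mapping[p] for p in paths
        }

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            blind_dataset(["x.tiff", "x.tiff"], seed=0)


class TestDrift:
    def test_injected_drift_recovered_exactly(self, small_invivo_config):
        cfg = small_invivo_config.replace(drift_px=3, seed=5)
        stack, truth = generate_timelapse(cfg)
        _, model = correct_drift(stack)
        assert np.array_equal(model.offsets, truth.drift_offsets)

    def test_no_drift_gives_zero_offsets(self, clean_invivo_config):
        stack, _ = generate_timelapse(clean_invivo_config)
        _, model = correct_drift(stack)
        assert np.abs(model.offsets).max() == 0

    def test_idempotent(self, small_invivo_config):
        stack, _ = generate_timelapse(small_invivo_config.replace(drift_px=2))
        corrected, _ = correct_drift(stack)
        _, second = correct_drift(corrected)
        assert np.abs(second.offsets).max() == 0

    def test_all_zero_frame_warns_and_keeps_zero_offset(self, clean_invivo_config):
        stack, _ = generate_timelapse(clean_invivo_config)
        data = stack.data.copy()
        data[5] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            _, model = correct_drift(stack.copy_with(data))
        assert tuple(model.offsets[5]) == (0, 0)


class TestBleedthrough:
    def test_zero_alpha_estimated_near_zero(self, small_invivo_config):
        cfg = small_invivo_config.replace(bleed_alpha=0.0, drift_px=0)
        stack, truth = generate_timelapse(cfg)
        model = estimate_bleedthrough(stack, _purkinje_only(truth))
        assert model.alpha <= 0.01

    def test_alpha_point_two_recovered(self, small_invivo_config):
        cfg = small_invivo_config.replace(bleed_alpha=0.2, drift_px=0, noise_sd=2.0)
        stack, truth = generate_timelapse(cfg)
        model = estimate_bleedthrough(stack, _purkinje_only(truth))
        assert model.alpha == pytest.approx(0.2, abs=0.01)

    def test_alpha_invariant_to_purkinje_brightness(self, small_invivo_config):
        cfg = small_invivo_config.replace(bleed_alpha=0.2, drift_px=0, noise_sd=0.0)
        stack, truth = generate_timelapse(cfg)
        doubled = stack.data.copy()
        doubled[:, :, 1] *= 2
        doubled[:, :, 0] = stack.data[:, :, 0] * 1.0
        # bleed contribution also doubles when the source doubles
        doubled[:, :, 0] += 0.2 * stack.data[:, :, 1]
        a1 = estimate_bleedthrough(stack, _purkinje_only(truth)).alpha
        a2 = estimate_bleedthrough(stack.copy_with(doubled), _purkinje_only(truth)).alpha
        assert a2 == pytest.approx(a1, rel=1e-6)

    def test_empty_mask_rejected(self, clean_invivo_config):
        stack, _ = generate_timelapse(clean_invivo_config)
        with pytest.raises(ValueError, match="empty"):
            estimate_bleedthrough(stack, np.zeros(stack.data.shape[1:2] + stack.data.shape[3:], bool))

    def test_subtraction_removes_purkinje_residual(self, small_invivo_config):
        cfg = small_invivo_config.replace(bleed_alpha=0.2, drift_px=0, noise_sd=2.0)
        stack, truth = generate_timelapse(cfg)
        model = estimate_bleedthrough(stack, _purkinje_only(truth))
        cleaned = subtract_bleedthrough(stack, model)
        residual = cleaned.data[0, :, 0][_purkinje_only(truth)]
        assert residual.mean() <= cfg.noise_sd
        assert cleaned.data.min() >= 0

    def test_noise_free_subtraction_is_exact(self, clean_invivo_config):
        from cerequant.synthgen import AMPLITUDE

        cfg = clean_invivo_config.replace(bleed_alpha=0.25)
        stack, truth = generate_timelapse(cfg)
        model = estimate_bleedthrough(stack, _purkinje_only(truth))
        cleaned = subtract_bleedthrough(stack, model)
        expected = AMPLITUDE * truth.microglia_masks.astype(float)
        assert np.allclose(cleaned.data[:, :, 0], expected, atol=1e-6)


class TestPCADenoise:
    def test_full_rank_is_identity(self, small_invivo_config):
        stack, _ = generate_timelapse(small_invivo_config)
        out = pca_denoise(stack, stack.n_timepoints)
        assert np.allclose(out.data, stack.data, atol=1e-6)

    def test_low_rank_signal_denoised(self, rng):
        # rank-2 temporal signal + noise: k=2 reconstruction beats the input
        t = np.arange(8)
        basis = np.stack([np.ones(8), np.sin(t)], axis=1)  # (T, 2)
        spatial = rng.uniform(0, 100, size=(2, 1, 2, 16, 16))
        truth_sig = np.einsum("tk,kzcyx->tzcyx", basis, spatial)
        truth_sig -= truth_sig.min()
        noisy = truth_sig + rng.normal(scale=5.0, size=truth_sig.shape)
        noisy = np.clip(noisy, 0, None)
        stack = TimelapseStack(noisy)
        out = pca_denoise(stack, 2)
        mse_in = ((noisy - truth_sig) ** 2).mean()
        mse_out = ((out.data - truth_sig) ** 2).mean()
        assert mse_out < mse_in

    def test_constant_stack_unchanged(self):
        stack = TimelapseStack(np.full((4, 2, 2, 8, 8), 7.0))
        out = pca_denoise(stack, 1)
        assert np.allclose(out.data, 7.0, atol=1e-9)

    def test_k_above_rank_warns_identity(self, small_invivo_config):
        stack, _ = generate_timelapse(small_invivo_config)
        with pytest.warns(UserWarning, match="rank"):
            out = pca_denoise(stack, stack.n_timepoints + 3)
        assert np.allclose(out.data, stack.data, atol=1e-6)


class TestLayerSplit:
    def test_slice_arithmetic(self):
        data = np.zeros((2, 101, 2, 8, 8))
        data[:, 30:60] = 1.0  # ML band
        data[:, 60:90] = 2.0  # PCL band
        stack = TimelapseStack(data)
        ml, pcl = split_layers(stack, pcl_start_z=60, n_slices=30)
        assert ml.data.shape[1] == pcl.data.shape[1] == 30
        assert np.all(ml.data == 1.0)
        assert np.all(pcl.data == 2.0)

    def test_out_of_range_rejected(self):
        stack = TimelapseStack(np.zeros((2, 40, 2, 8, 8)))
        with pytest.raises(ValueError):
            split_layers(stack, pcl_start_z=30, n_slices=20)
        with pytest.raises(ValueError):
            split_layers(stack, pcl_start_z=10, n_slices=20)

    def test_purkinje_somas_fall_in_pcl_substack(self, clean_invivo_config):
        # deep enough that the soma monolayer sits inside the PCL with slack
        stack, truth = generate_timelapse(
            clean_invivo_config.replace(zstack_depth_um=60)
        )
        pcl_start = truth.layer_z["PCL"][0]
        n = min(pcl_start, stack.n_slices - pcl_start)
        # soma voxels = purkinje voxels below the boundary
        soma_vox = truth.purkinje_mask.copy()
        soma_vox[:pcl_start] = False
        for boundary in (pcl_start - 2, pcl_start, pcl_start + 2):
            _, pcl = split_layers(stack, boundary, min(n, boundary, stack.n_slices - boundary))
            z0, z1 = boundary, boundary + pcl.data.shape[1]
            frac = soma_vox[z0:z1].sum() / soma_vox.sum()
            assert frac >= 0.95


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        data = rng.uniform(size=(3, 1, 2, 8, 8))
        assert np.array_equal(max_project(data), data[:, 0])

    def test_disjoint_disks_union(self):
        plane = np.zeros((2, 16, 16))
        plane[0, 2:5, 2:5] = 1.0
        plane[1, 10:13, 10:13] = 1.0
        proj = max_project(plane, z_axis=0)
        assert proj.sum() == 18.0

    def test_matches_brute_force(self, rng):
        data = rng.uniform(size=(2, 5, 2, 12, 12))
        proj = max_project(data)
        brute = np.empty((2, 2, 12, 12))
        for t in range(2):
            for c in range(2):
                for y in range(12):
                    for x in range(12):
                        brute[t, c, y, x] = max(data[t, z, c, y, x] for z in range(5))
        assert np.array_equal(proj, brute)
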