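"""Motility index, surveillance ratio, and injury-front convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cerequant.dynamics import (
    detect_front,
    injury_convergence,
    motility_index,
    surveillance_ratio,
)
from cerequant.synthgen import SynthConfig, _circle_polygon, generate_timelapse


def _brute_force_mi(a, b):
    ext = ret = stab = 0
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            if a[y, x] and b[y, x]:
                stab += 1
            elif a[y, x]:
                ret += 1
            elif b[y, x]:
                ext += 1
    return (ext + ret) / stab


class TestMotilityIndex:
    def test_identical_masks_give_zero(self):
        m = np.zeros((16, 16), bool)
        m[4:10, 4:10] = True
        res = motility_index([m, m, m])
        assert res.motility_index == 0.0
        assert np.all(res.motility_per_pair == 0.0)

    def test_ten_new_pixels_on_hundred(self):
        a = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True  # 100 px
        b = a.copy()
        b[15, 0:10] = True  # 10 new px
        res = motility_index([a, b])
        assert res.motility_index == pytest.approx(0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=arrays(bool, (64, 64), elements=st.booleans()),
        b=arrays(bool, (64, 64), elements=st.booleans()),
    )
    def test_matches_brute_force_oracle(self, a, b):
        if not (a & b).any():
            return
        res = motility_index([a, b])
        assert res.motility_index == pytest.approx(_brute_force_mi(a, b))

    def test_zero_stable_pair_excluded_with_warning(self):
        a = np.zeros((8, 8), bool)
        a[0, 0] = True
        b = np.zeros((8, 8), bool)
        b[7, 7] = True
        c = b.copy()
        with pytest.warns(UserWarning, match="zero stable"):
            res = motility_index([a, b, c])
        assert len(res.motility_per_pair) == 1  # only the (b, c) pair

    def test_needs_two_timepoints(self):
        with pytest.raises(ValueError):
            motility_index([np.ones((4, 4), bool)])


class TestSurveillanceRatio:
    def test_static_masks_give_one(self):
        m = np.zeros((16, 16), bool)
        m[2:8, 2:8] = True
        assert surveillance_ratio([m, m, m]) == 1.0

    def test_union_growth(self):
        a = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True
        b = np.zeros((20, 20), bool)
        b[5:15, 0:10] = True  # union = 150
        assert surveillance_ratio([a, b]) == pytest.approx(1.5)

    def test_monotone_in_generator_turnover(self):
        srs = []
        for m in (0.0, 0.05, 0.1, 0.2):
            cfg = SynthConfig(
                image_shape=(96, 96), zstack_depth_um=32, noise_sd=0,
                drift_px=0, process_turnover=m, seed=13,
            )
            _, truth = generate_timelapse(cfg)
            masks = [truth.layer_projection("ML", t) for t in range(12)]
            srs.append(surveillance_ratio(masks))
        assert all(b > a for a, b in zip(srs, srs[1:]))

    def test_empty_first_mask_rejected(self):
        a = np.zeros((8, 8), bool)
        b = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="empty"):
            surveillance_ratio([a, b])

    def test_sr_at_least_one(self):
        # equality iff nothing ever appears outside mask 1
        a = np.zeros((8, 8), bool)
        a[2:6, 2:6] = True
        shrunk = a.copy()
        shrunk[2] = False
        assert surveillance_ratio([a, shrunk]) == 1.0


class TestFrontDetection:
    def test_annulus_front_is_circle(self):
        ny = nx = 128
        yy, xx = np.mgrid[0:ny, 0:nx]
        rr = np.hypot(yy - 64, xx - 64)
        mask = (rr >= 30) & (rr <= 50)
        core = _circle_polygon(64, 64, 5)
        front = detect_front(mask, core)
        from cerequant.containers import polygon_area

        assert polygon_area(front) == pytest.approx(np.pi * 30**2, rel=0.05)

    def test_microglia_touching_core_gives_core_area(self):
        ny = nx = 64
        yy, xx = np.mgrid[0:ny, 0:nx]
        core_r = 8
        core = _circle_polygon(32, 32, core_r)
        mask = np.hypot(yy - 32, xx - 32) > core_r  # everything but the core
        front = detect_front(mask, core)
        from cerequant.containers import polygon_area

        assert polygon_area(front) == pytest.approx(np.pi * core_r**2, rel=0.15)

    def test_empty_mask_gives_frame_rectangle(self):
        core = _circle_polygon(32, 32, 5)
        with pytest.warns(UserWarning, match="no microglia"):
            front = detect_front(np.zeros((64, 64), bool), core)
        from cerequant.containers import polygon_area

        assert polygon_area(front) == pytest.approx(63 * 63)


class TestInjuryConvergence:
    def test_first_timepoint_is_one(self):
        sq = lambda s: np.array([[0, 0], [s, 0], [s, s], [0, s]], float)
        series = injury_convergence([sq(30), sq(25)], sq(10))
        assert series.proximity[0] == 1.0

    def test_collapsed_front_is_zero(self):
        sq = lambda s: np.array([[0, 0], [s, 0], [s, s], [0, s]], float)
        series = injury_convergence([sq(30), sq(10)], sq(10))
        assert series.proximity[1] == 0.0

    def test_square_shoelace_example(self):
        sq = lambda s: np.array([[0, 0], [s, 0], [s, s], [0, s]], float)
        series = injury_convergence([sq(30), sq(20)], sq(10))
        assert series.proximity[1] == pytest.approx((400 - 100) / (900 - 100))

    def test_degenerate_first_front_rejected(self):
        sq = lambda s: np.array([[0, 0], [s, 0], [s, s], [0, s]], float)
        with pytest.raises(ValueError):
            injury_convergence([sq(10), sq(10)], sq(10))

    def test_generator_series_non_increasing(self):
        from cerequant.segment import binarize_objects
        from cerequant.synthgen import generate_injury_series

        cfg = SynthConfig(
            image_shape=(128, 128), noise_sd=2.0, injury_rate_px=2.5, seed=6
        )
        stack, truth = generate_injury_series(cfg)
        fronts = []
        for t in range(cfg.n_timepoints):
            proj = stack.data[t, :, 0].max(axis=0)
            mask = binarize_objects(proj, 500, min_size=4).data
            fronts.append(detect_front(mask, truth.core_polygon))
        series = injury_convergence(fronts, truth.core_polygon)
        assert np.all(np.diff(series.proximity) <= 0.02)
        assert np.allclose(series.proximity, truth.proximity, atol=0.05)


class TestLayerMotilityContrast:
    def test_higher_pcl_turnover_yields_higher_pcl_motility(self):
        cfg = SynthConfig(
            image_shape=(96, 96), zstack_depth_um=32, noise_sd=0, drift_px=0,
            process_turnover={"ML": 0.05, "PCL": 0.15}, seed=21,
        )
        _, truth = generate_timelapse(cfg)
        mi = {}
        for layer in ("ML", "PCL"):
            masks = [truth.layer_projection(layer, t) for t in range(12)]
            mi[layer] = motility_index(masks).motility_index
        assert mi["PCL"] > mi["ML"]
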