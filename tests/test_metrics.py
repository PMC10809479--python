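"""PICoV, quadrant summaries, colorization and density metrics."""
import math

import numpy as np
import pytest
from matplotlib import colormaps

from picov.datatypes import OD, OS, PICoVMap
from picov.metrics import (colorize_picov, compute_density_series,
                           compute_picov_map, summarize_picov)
from picov.segmentation import segment_vessels


class TestComputePicov:
    def test_matches_closed_form(self, rng):
        series = rng.uniform(0.05, 1.0, size=(10, 500))
        stack = series.reshape(10, 1, 500)
        pic = compute_picov_map(stack, mean_floor=0.0)
        oracle = series.std(axis=0, ddof=1) / series.mean(axis=0)
        assert np.max(np.abs(pic.values[0] - oracle)) < 1e-12

    def test_worked_series(self):
        # five frames at 0.1 and five at 0.3: sample SD sqrt(0.1/9),
        # mean 0.2, CV = sqrt(10)/6 = 0.527
        stack = np.array([0.1] * 5 + [0.3] * 5).reshape(10, 1, 1)
        cv = compute_picov_map(stack).values[0, 0]
        assert abs(cv - 0.527) < 1e-3
        assert abs(cv - math.sqrt(10) / 6) < 1e-12

    def test_constant_series_has_zero_cv(self):
        stack = np.full((10, 4, 4), 0.5)
        pic = compute_picov_map(stack)
        assert pic.validity.all()
        assert not pic.values.any()

    def test_scale_invariance(self, rng):
        frames = rng.uniform(0.1, 0.9, size=(8, 6, 6))
        a = compute_picov_map(frames).values
        b = compute_picov_map(0.5 * frames).values
        assert np.allclose(a, b)

    def test_mean_floor_invalidates_dark_pixels(self):
        stack = np.zeros((10, 2, 2))
        stack[:, 0, 0] = 0.5
        stack[:, 0, 1] = 0.005  # below the 0.01 floor
        pic = compute_picov_map(stack)
        assert pic.validity[0, 0]
        assert not pic.validity[0, 1]
        assert pic.values[0, 1] == 0.0

    def test_external_validity_intersected(self):
        stack = np.full((5, 2, 2), 0.5)
        ext = np.array([[True, False], [True, True]])
        pic = compute_picov_map(stack, validity=ext)
        assert not pic.validity[0, 1]

    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            compute_picov_map(np.zeros((1, 4, 4)))


class TestSummarize:
    def test_uniform_map_all_quadrants_equal(self):
        pic = PICoVMap(np.full((40, 40), 0.2), np.ones((40, 40), dtype=bool))
        eye, q = summarize_picov(pic, OD)
        assert eye == pytest.approx(0.2)
        assert all(v == pytest.approx(0.2) for v in q.as_dict().values())

    def test_laterality_mirrors_temporal_side(self):
        vals = np.zeros((40, 40))
        vals[:, :20] = 0.3  # left half hot
        pic = PICoVMap(vals, np.ones((40, 40), dtype=bool))
        _, q_od = summarize_picov(pic, OD)  # left is temporal in OD
        _, q_os = summarize_picov(pic, OS)  # left is nasal in OS
        assert q_od.picov_ST == pytest.approx(0.3)
        assert q_od.picov_SN == pytest.approx(0.0)
        assert q_os.picov_SN == pytest.approx(0.3)
        assert q_os.picov_ST == pytest.approx(0.0)

    def test_superior_is_image_top(self):
        vals = np.zeros((40, 40))
        vals[:20, :] = 0.3
        pic = PICoVMap(vals, np.ones((40, 40), dtype=bool))
        _, q = summarize_picov(pic, OD)
        assert q.picov_ST == pytest.approx(0.3)
        assert q.picov_IT == pytest.approx(0.0)

    def test_empty_quadrant_is_nan(self):
        valid = np.zeros((40, 40), dtype=bool)
        valid[:20, :20] = True
        pic = PICoVMap(np.full((40, 40), 0.1), valid)
        _, q = summarize_picov(pic, OD)
        assert not math.isnan(q.picov_ST)
        assert math.isnan(q.picov_IN)

    def test_median_reduction(self):
        vals = np.zeros((4, 4))
        vals[0] = [0.1, 0.1, 0.1, 10.0]
        valid = np.zeros((4, 4), dtype=bool)
        valid[0] = True
        eye, _ = summarize_picov(PICoVMap(vals, valid), OD,
                                 reduction="median")
        assert eye == pytest.approx(0.1)

    def test_all_invalid_raises(self):
        pic = PICoVMap(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            summarize_picov(pic, OD)


class TestColorize:
    def test_cap_saturates(self):
        vals = np.array([[0.0, 0.4, 0.7]])
        pic = PICoVMap(vals, np.ones_like(vals, dtype=bool))
        rgb = colorize_picov(pic, cap=0.4)
        assert np.array_equal(rgb[0, 1], rgb[0, 2])  # both at the cap
        low = np.round(np.array(colormaps["jet"](0.0)[:3]) * 255)
        high = np.round(np.array(colormaps["jet"](1.0)[:3]) * 255)
        assert np.array_equal(rgb[0, 0], low.astype(np.uint8))
        assert np.array_equal(rgb[0, 1], high.astype(np.uint8))

    def test_invalid_pixels_black(self):
        vals = np.full((2, 2), 0.2)
        valid = np.array([[True, False], [True, True]])
        rgb = colorize_picov(PICoVMap(vals, valid))
        assert not rgb[0, 1].any()
        assert rgb[0, 0].any()

    def test_rejects_nonpositive_cap(self):
        pic = PICoVMap(np.zeros((2, 2)), np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            colorize_picov(pic, cap=0.0)


class TestDensity:
    def test_toy_mask(self):
        # 4 ones among 16 pixels: PD = 4/12, VD on the 1-px skeleton
        frame = np.zeros((4, 4))
        frame[:2, :2] = 1.0
        d = compute_density_series(frame, segmenter=None)
        assert d.mean_pd == pytest.approx(4 / 12)
        assert d.mean_vd <= d.mean_pd

    def test_ones_to_total_variant(self):
        frame = np.zeros((4, 4))
        frame[:2, :2] = 1.0
        d = compute_density_series(frame, segmenter=None,
                                   pd_definition="ones_to_total")
        assert d.mean_pd == pytest.approx(4 / 16)
        assert d.pd_definition == "ones_to_total"

    def test_identical_frames_zero_sd(self):
        frame = np.zeros((6, 6))
        frame[2:4] = 1.0
        frames = np.repeat(frame[None], 5, axis=0)
        d = compute_density_series(frames, segmenter=None)
        assert d.sd_pd == 0.0
        assert d.sd_vd == 0.0

    def test_vd_never_exceeds_pd(self, dvc_stack):
        stack, _ = dvc_stack
        d = compute_density_series(stack.frames, segment_vessels)
        assert (d.vd <= d.pd).all()
        assert len(d.pd) == stack.n_frames

    def test_validity_restricts_denominator(self):
        frame = np.zeros((4, 4))
        frame[0, 0] = 1.0
        validity = np.zeros((4, 4), dtype=bool)
        validity[:2, :2] = True
        d = compute_density_series(frame, segmenter=None, validity=validity)
        assert d.mean_pd == pytest.approx(1 / 3)

    def test_all_ones_frame_is_error(self):
        with pytest.raises(ZeroDivisionError):
            compute_density_series(np.ones((3, 4, 4)), segmenter=None)

    def test_rejects_unknown_definition(self):
        with pytest.raises(ValueError):
            compute_density_series(np.zeros((2, 4, 4)), None,
                                   pd_definition="fraction")
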