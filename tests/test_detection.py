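"""HSB filtering, view masking and centroid localization."""

from __future__ import annotations

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from strobolabel.detection import (
    DetectionStatus,
    HSBBounds,
    ViewMaskSet,
    apply_view_mask,
    detect_all,
    detect_marker,
    filter_color,
)
from strobolabel.simulate import Occlusion, SyntheticVideo, true_center

from conftest import random_binary_mask, render_frames, small_config


def hsb_image(h_deg: float, s: float, v: float, shape=(6, 6)) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb(h_deg / 360.0, s, v)
    px = np.array([r, g, b]) * 255.0
    return np.tile(np.round(px).astype(np.uint8), (*shape, 1))


def brute_force_largest_centroid(mask: np.ndarray, min_area: int):
    """Independent oracle: label 8-connected components by BFS and return
    (centroid_xy, area) of the largest with area >= min_area, with the
    same (area desc, centroid y, centroid x) tie-break."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            pix = []
            while stack:
                y, x = stack.pop()
                pix.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(pix)
    cands = [p for p in comps if len(p) >= min_area]
    if not cands:
        return None, 0, 0
    def key(pix):
        ys = sum(p[0] for p in pix) / len(pix)
        xs = sum(p[1] for p in pix) / len(pix)
        return (-len(pix), ys, xs)
    cands.sort(key=key)
    best = cands[0]
    cy = sum(p[0] for p in best) / len(best)
    cx = sum(p[1] for p in best) / len(best)
    return (cx, cy), len(best), len(cands)


class TestHSBBounds:
    def test_invalid_saturation_order_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            HSBBounds("x", (0, 0.9, 0), (10, 0.1, 1))

    def test_hue_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="hue"):
            HSBBounds("x", (360.0, 0, 0), (10, 1, 1))

    def test_wrap_flag(self):
        assert HSBBounds("r", (350, 0, 0), (10, 1, 1)).wraps
        assert not HSBBounds("g", (100, 0, 0), (140, 1, 1)).wraps


class TestFilterColor:
    def test_black_image_below_brightness_floor_is_all_false(self):
        img = np.zeros((5, 5, 3), np.uint8)
        bounds = HSBBounds("any", (0, 0, 0.1), (359, 1, 1))
        assert not filter_color(img, bounds).any()

    def test_uniform_in_gamut_image_is_all_true(self):
        img = hsb_image(120, 0.9, 0.9)
        bounds = HSBBounds("g", (100, 0.5, 0.5), (140, 1, 1))
        assert filter_color(img, bounds).all()

    def test_wraparound_hue_interval(self):
        bounds = HSBBounds("red", (350, 0.5, 0.5), (10, 1, 1))
        assert filter_color(hsb_image(5, 0.9, 0.9), bounds).all()
        assert not filter_color(hsb_image(180, 0.9, 0.9), bounds).any()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        img=hnp.arrays(np.uint8, (5, 7, 3)),
        lo_h=st.floats(0, 359.9), hi_h=st.floats(0, 359.9),
        lo_s=st.floats(0, 1), hi_s=st.floats(0, 1),
        lo_v=st.floats(0, 1), hi_v=st.floats(0, 1),
    )
    def test_matches_scalar_reference_pixelwise(self, img, lo_h, hi_h, lo_s, hi_s, lo_v, hi_v):
        """The vectorized filter agrees with colorsys-based scalar membership."""
        lo_s, hi_s = sorted((lo_s, hi_s))
        lo_v, hi_v = sorted((lo_v, hi_v))
        bounds = HSBBounds("t", (lo_h, lo_s, lo_v), (hi_h, hi_s, hi_v))
        mask = filter_color(img, bounds)
        for y in range(img.shape[0]):
            for x in range(img.shape[1]):
                r, g, b = img[y, x] / 255.0
                h, s, v = colorsys.rgb_to_hsv(r, g, b)
                expected = bounds.contains((h * 360.0) % 360.0, s, v)
                assert mask[y, x] == expected, (y, x, img[y, x])


class TestViewMasks:
    def test_identity_and_annihilator(self):
        rng = np.random.default_rng(0)
        mask = random_binary_mask(rng, (10, 10))
        assert (apply_view_mask(mask, np.ones((10, 10), bool)) == mask).all()
        assert not apply_view_mask(mask, np.zeros((10, 10), bool)).any()

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError, match="shape"):
            apply_view_mask(np.ones((4, 4), bool), np.ones((5, 5), bool))

    def test_each_view_keeps_only_its_own_blob(self):
        img = np.zeros((20, 10), bool)
        img[2:5, 2:5] = True    # top blob
        img[14:17, 2:5] = True  # bottom blob
        views = ViewMaskSet({
            "bottom": np.r_[np.ones((10, 10), bool), np.zeros((10, 10), bool)],
            "side": np.r_[np.zeros((10, 10), bool), np.ones((10, 10), bool)],
        })
        top = apply_view_mask(img, views.masks["bottom"])
        bot = apply_view_mask(img, views.masks["side"])
        assert top.sum() == 9 and top[2:5, 2:5].all()
        assert bot.sum() == 9 and bot[14:17, 2:5].all()

    def test_overlapping_masks_rejected(self):
        a = np.zeros((5, 5), bool); a[0:3] = True
        b = np.zeros((5, 5), bool); b[2:5] = True
        with pytest.raises(ValueError, match="overlap"):
            ViewMaskSet({"bottom": a, "side": b})

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ViewMaskSet({"bottom": np.zeros((5, 5), bool),
                         "side": np.ones((5, 5), bool)})


class TestDetectMarker:
    def test_empty_mask_is_missing(self):
        det = detect_marker(np.zeros((10, 10), bool))
        assert det.status is DetectionStatus.MISSING
        assert det.centroid is None and det.area == 0

    def test_square_centroid(self):
        mask = np.zeros((40, 40), bool)
        mask[20:25, 10:15] = True  # 5×5 square, top-left (x=10, y=20)
        det = detect_marker(mask)
        assert det.status is DetectionStatus.FOUND
        assert det.centroid == pytest.approx((12.0, 22.0))
        assert det.area == 25

    def test_ambiguous_when_runner_up_at_least_half(self):
        mask = np.zeros((40, 40), bool)
        mask[0:10, 0:10] = True    # area 100
        mask[20:26, 20:30] = True  # area 60 ≥ 0.5 × 100
        det = detect_marker(mask)
        assert det.status is DetectionStatus.AMBIGUOUS
        assert det.area == 100
        assert det.centroid == pytest.approx((4.5, 4.5))
        assert det.n_components == 2

    def test_small_runner_up_is_unambiguous(self):
        mask = np.zeros((40, 40), bool)
        mask[0:10, 0:10] = True   # area 100
        mask[20:24, 20:30] = True  # area 40 < 50
        assert detect_marker(mask).status is DetectionStatus.FOUND

    def test_min_area_filters_noise(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        assert detect_marker(mask, min_area=9).status is DetectionStatus.MISSING

    def test_equal_area_tie_breaks_deterministically(self):
        mask = np.zeros((20, 20), bool)
        mask[10:13, 10:13] = True
        mask[2:5, 2:5] = True
        det = detect_marker(mask)
        # equal areas: the component with the smaller (y, x) centroid wins
        assert det.centroid == pytest.approx((3.0, 3.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), p=st.floats(0.05, 0.6))
    def test_centroid_matches_brute_force_oracle(self, seed, p):
        """Largest-component centroid equals an independent BFS scan."""
        rng = np.random.default_rng(seed)
        mask = random_binary_mask(rng, (25, 25), p)
        det = detect_marker(mask, min_area=3)
        oracle_centroid, oracle_area, oracle_n = brute_force_largest_centroid(mask, 3)
        if oracle_centroid is None:
            assert det.status is DetectionStatus.MISSING
        else:
            assert det.area == oracle_area
            assert det.n_components == oracle_n
            assert det.centroid[0] == pytest.approx(oracle_centroid[0], abs=1e-9)
            assert det.centroid[1] == pytest.approx(oracle_centroid[1], abs=1e-9)


class TestDetectAll:
    def test_recovers_all_eight_markers_near_truth(self, small_frames, small_cfg,
                                                   small_bounds, small_views):
        uv = small_frames[0]
        dets = detect_all(uv, small_bounds, small_views)
        assert len(dets) == 8
        paw_of = small_cfg.color_to_paw
        for d in dets:
            assert d.status is DetectionStatus.FOUND
            tx, ty = true_center(small_cfg, paw_of[d.color_name], d.view_name, 0)
            err = np.hypot(d.centroid[0] - tx, d.centroid[1] - ty)
            assert err <= 1.0

    def test_occluded_marker_reported_missing(self, small_cfg, small_bounds, small_views):
        video = SyntheticVideo(small_cfg, {Occlusion(0, "left_front_side")})
        frames = render_frames(video)
        dets = detect_all(frames[0], small_bounds, small_views)
        missing = [d for d in dets if d.status is DetectionStatus.MISSING]
        assert len(missing) == 1
        d = missing[0]
        assert small_cfg.color_to_paw[d.color_name] == "left_front"
        assert d.view_name == "side"

    def test_all_dark_frame_gives_eight_missing(self, small_bounds, small_views, small_cfg):
        from strobolabel.frames import Frame, Modality

        f = Frame(0, np.zeros((small_cfg.height, small_cfg.width, 3), np.uint8),
                  modality=Modality.UV)
        dets = detect_all(f, small_bounds, small_views)
        assert all(d.status is DetectionStatus.MISSING for d in dets)

    def test_rejects_non_uv_frame(self, small_frames, small_bounds, small_views):
        with pytest.raises(ValueError, match="not a UV frame"):
            detect_all(small_frames[1], small_bounds, small_views)

    def test_deterministic(self, small_frames, small_bounds, small_views):
        a = detect_all(small_frames[0], small_bounds, small_views)
        b = detect_all(small_frames[0], small_bounds, small_views)
        assert a == b
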