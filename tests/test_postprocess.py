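"""Postprocessing: mask merging, caudal correction, component labeling
and corner extraction against constructed oracles."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from spinemetrics.levels import LEVELS
from spinemetrics.postprocess import (
    VertebraComponent,
    caudal_correction,
    components_to_vertebrae,
    extract_corners,
    femoral_landmarks,
    merge_neck_into_spine,
    sacral_landmarks,
)
from spinemetrics.preprocess import RoiWindow


def blob(shape, y0, y1, x0, x1):
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    return m


def component_from(mask):
    ys, xs = np.nonzero(mask)
    return VertebraComponent(
        pixels=np.column_stack([xs, ys]),
        centroid=(float(xs.mean()), float(ys.mean())),
        area=len(xs),
    )


def identity_window(name, shape):
    return RoiWindow(name, "frontal", 0, shape[1], 0, shape[0],
                     target_hw=shape)


class TestMergeNeck:
    def test_empty_neck_passes_spine_through(self):
        spine = blob((100, 50), 10, 90, 10, 40)
        w = identity_window("spine", (100, 50))
        wn = identity_window("neck", (100, 50))
        out, flags = merge_neck_into_spine(spine, np.zeros((100, 50), bool), w, wn)
        assert flags["neck_empty"] and np.array_equal(out, spine)

    def test_neck_c7_transferred_into_empty_spine(self):
        neck = blob((100, 50), 5, 20, 20, 40)
        w = identity_window("spine", (100, 50))
        wn = identity_window("neck", (100, 50))
        out, flags = merge_neck_into_spine(
            np.zeros((100, 50), bool), neck, w, wn
        )
        assert not flags["neck_empty"]
        assert out[10, 30] and out.sum() >= neck.sum()

    def test_cranial_spine_blob_overlapping_c7_removed(self):
        # oracle: set algebra on constructed blobs
        shape = (120, 60)
        c7 = blob(shape, 10, 28, 20, 45)
        wrong_c7 = blob(shape, 8, 24, 22, 43)  # spine net's bad C7
        t1 = blob(shape, 40, 58, 20, 45)
        spine = wrong_c7 | t1
        w = identity_window("spine", shape)
        wn = identity_window("neck", shape)
        out, _ = merge_neck_into_spine(spine, c7, w, wn)
        assert not out[9, 30] or c7[9, 30]  # wrong C7 gone
        assert out[45, 30]  # T1 kept
        assert out[c7].all()  # neck C7 pasted


class TestCaudalCorrection:
    def test_blob_below_sacral_line_removed(self):
        spine = blob((100, 60), 20, 35, 10, 50) | blob((100, 60), 80, 95, 10, 50)
        out, _ = caudal_correction(spine, (5.0, 60.0), (55.0, 60.0))
        assert out[25, 30] and not out[85, 30]

    def test_blob_above_retained(self):
        spine = blob((100, 60), 20, 35, 10, 50)
        out, _ = caudal_correction(spine, (5.0, 60.0), (55.0, 60.0))
        assert np.array_equal(out, spine)

    def test_straddling_blob_with_centroid_above_retained(self):
        spine = blob((100, 60), 50, 68, 10, 50)  # centroid y = 58.5 < 60
        out, _ = caudal_correction(spine, (5.0, 60.0), (55.0, 60.0))
        assert np.array_equal(out, spine)

    def test_no_sacral_points_passthrough_flagged(self):
        spine = blob((100, 60), 80, 95, 10, 50)
        out, flags = caudal_correction(spine, None, None)
        assert flags["no_sacral_points"] and np.array_equal(out, spine)


class TestComponentsToVertebrae:
    def test_phantom_components_labeled_in_order(self, default_masks):
        comps, flags = components_to_vertebrae(
            default_masks.view("frontal")["vertebra"]
        )
        assert flags["complete"] and len(comps) == 18
        assert [c.level for c in comps] == list(LEVELS)

    def test_seventeen_components_incomplete(self):
        m = np.zeros((400, 60), dtype=bool)
        for i in range(17):
            m[i * 22 : i * 22 + 12, 10:50] = True
        comps, flags = components_to_vertebrae(m)
        assert not flags["complete"] and len(comps) == 17

    def test_speck_filtered_to_18(self):
        m = np.zeros((460, 60), dtype=bool)
        for i in range(18):
            m[i * 25 : i * 25 + 14, 10:50] = True
        m[455:457, 2:4] = True  # 4-px speck
        comps, flags = components_to_vertebrae(m)
        assert flags["complete"] and len(comps) == 18

    def test_reasonableness_monotone_under_component_removal(self):
        m = np.zeros((460, 60), dtype=bool)
        for i in range(18):
            m[i * 25 : i * 25 + 14, 10:50] = True
        _, flags_full = components_to_vertebrae(m)
        m2 = m.copy()
        m2[0:14] = False  # drop one vertebra
        _, flags_less = components_to_vertebrae(m2)
        assert flags_full["complete"] and not flags_less["complete"]


class TestExtractCorners:
    def test_axis_aligned_rectangle_corners(self):
        m = blob((60, 80), 20, 40, 10, 54)  # 20 x 44 rectangle
        c = extract_corners(component_from(m), "frontal")
        assert np.allclose(c["superior_left"], (10, 20), atol=1.0)
        assert np.allclose(c["superior_right"], (53, 20), atol=1.0)
        assert np.allclose(c["inferior_left"], (10, 39), atol=1.0)
        assert np.allclose(c["inferior_right"], (53, 39), atol=1.0)

    @pytest.mark.parametrize("angle", [10.0, 20.0, -15.0])
    def test_rotated_rectangle_corners_match_analytic_oracle(self, angle):
        a = np.deg2rad(angle)
        w, h = 44.0, 20.0
        cx, cy = 60.0, 60.0
        u = np.array([np.cos(a), -np.sin(a)])
        n = np.array([np.sin(a), np.cos(a)])
        corners = [
            cx * np.array([1, 0]) + cy * np.array([0, 1])
            + sx * u * w / 2 + sy * n * h / 2
            for sx, sy in ((-1, -1), (1, -1), (-1, 1), (1, 1))
        ]
        mask = np.zeros((120, 120), dtype=bool)
        ring = [corners[0], corners[1], corners[3], corners[2]]
        rr, cc = draw_polygon([p[1] for p in ring], [p[0] for p in ring],
                              shape=mask.shape)
        mask[rr, cc] = True
        got = extract_corners(component_from(mask), "frontal")
        want = {
            "superior_left": corners[0],
            "superior_right": corners[1],
            "inferior_left": corners[2],
            "inferior_right": corners[3],
        }
        for k in want:
            assert np.hypot(*(np.array(got[k]) - want[k])) <= 1.5, (k, angle)

    def test_degenerate_component_raises(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:35, 10] = True  # 1-px line
        with pytest.raises(ValueError):
            extract_corners(component_from(m), "frontal")


class TestPointLandmarks:
    def test_disk_centroids_within_half_pixel(self):
        m1 = np.zeros((80, 80), dtype=bool)
        m2 = np.zeros((80, 80), dtype=bool)
        rr, cc = draw_disk((30.0, 25.0), 6.0)
        m1[rr, cc] = True
        rr, cc = draw_disk((50.0, 60.0), 6.0)
        m2[rr, cc] = True
        a, p, mid = sacral_landmarks(m1, m2)
        assert np.allclose(a, (25.0, 30.0), atol=0.5)
        assert np.allclose(p, (60.0, 50.0), atol=0.5)
        assert mid == ((a[0] + p[0]) / 2, (a[1] + p[1]) / 2)

    def test_empty_sacral_mask_fails(self):
        m = np.zeros((40, 40), dtype=bool)
        m2 = m.copy()
        m2[10:14, 10:14] = True
        assert sacral_landmarks(m, m2) is None

    def test_femoral_single_head_flagged(self):
        m1 = np.zeros((60, 60), dtype=bool)
        rr, cc = draw_disk((30.0, 30.0), 8.0)
        m1[rr, cc] = True
        centers, mid, flags = femoral_landmarks(m1, np.zeros_like(m1))
        assert flags["single_head"] and len(centers) == 1
        assert np.allclose(mid, centers[0])

    def test_femoral_midpoint_is_exact_average(self):
        m1 = np.zeros((60, 120), dtype=bool)
        m2 = np.zeros((60, 120), dtype=bool)
        rr, cc = draw_disk((30.0, 25.0), 8.0)
        m1[rr, cc] = True
        rr, cc = draw_disk((30.0, 95.0), 8.0)
        m2[rr, cc] = True
        centers, mid, flags = femoral_landmarks(m1, m2)
        assert not flags["single_head"]
        assert mid == (
            (centers[0][0] + centers[1][0]) / 2,
            (centers[0][1] + centers[1][1]) / 2,
        )
        assert femoral_landmarks(np.zeros_like(m1), np.zeros_like(m2)) is None
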