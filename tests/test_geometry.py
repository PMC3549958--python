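"""Midline estimation, landmarks, head detection and bending angle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from larvatrack.geometry import (
    BendClass,
    bending_angle,
    classify_bend,
    detect_head,
    estimate_spine,
    orient_by_motion,
    place_landmarks,
)
from larvatrack.segmentation import extract_contours


def bent_band_mask(amplitude: float = 18.0, halfwidth: float = 4.0):
    """Sinusoidally bent band with a known midline (the oracle)."""
    H, W = 120, 220
    xs = np.linspace(30, 190, 1000)
    ys = 60 + amplitude * np.sin((xs - 30) / 160 * 2 * np.pi)
    midline = np.column_stack([ys, xs])
    tree = cKDTree(midline)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d, _ = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
    return d.reshape(H, W) < halfwidth, tree


class TestEstimateSpine:
    def test_rectangle_midline_recovered(self, rect_mask):
        (c,) = extract_contours(rect_mask)
        for seed in range(5):
            sp = estimate_spine(c, seed=seed)
            assert np.abs(sp.points[:, 0] - 13.5).max() <= 1.0
            assert sp.arc_length == pytest.approx(60, abs=2)

    def test_bent_band_midline_recovered(self):
        mask, tree = bent_band_mask()
        (c,) = extract_contours(mask)
        sp = estimate_spine(c, seed=4)
        d, _ = tree.query(sp.points)
        assert d.mean() <= 1.5

    def test_deterministic_given_seed(self, rect_mask):
        (c,) = extract_contours(rect_mask)
        a = estimate_spine(c, seed=11)
        b = estimate_spine(c, seed=11)
        np.testing.assert_array_equal(a.points, b.points)

    def test_thin_shape_rejected(self):
        m = np.zeros((10, 40), dtype=bool)
        m[5, 5:35] = True  # 1-px line: erosion empties it
        (c,) = extract_contours(m)
        with pytest.raises(ValueError, match="too thin"):
            estimate_spine(c)

    def test_near_circular_shape_rejected(self):
        yy, xx = np.mgrid[0:40, 0:40]
        m = (yy - 20) ** 2 + (xx - 20) ** 2 < 15**2
        (c,) = extract_contours(m)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_spine(c)


class TestLandmarks:
    def test_straight_spine_equal_spacing(self):
        pts = np.column_stack([np.zeros(61), np.arange(61.0)])
        lm = place_landmarks(pts)
        np.testing.assert_allclose(lm[:, 1], [0, 10, 20, 30, 40, 50, 60])

    @staticmethod
    def _arc_position(points: np.ndarray, q: np.ndarray) -> float:
        """Exact arc position of q by projection onto the nearest segment."""
        seg = np.diff(points, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        arc = np.concatenate(([0.0], seg_len.cumsum()))
        best_d, best_s = np.inf, 0.0
        for i in range(len(seg)):
            if seg_len[i] == 0:
                continue
            t = np.clip((q - points[i]) @ seg[i] / seg_len[i] ** 2, 0, 1)
            p = points[i] + t * seg[i]
            d = np.linalg.norm(q - p)
            if d < best_d:
                best_d, best_s = d, arc[i] + t * seg_len[i]
        return best_s

    def test_centre_landmark_at_half_arc(self, rect_mask):
        (c,) = extract_contours(rect_mask)
        sp = estimate_spine(c, seed=0)
        s = self._arc_position(sp.points, sp.landmarks[3])
        assert s / sp.arc_length == pytest.approx(0.5, abs=0.01)

    def test_arc_spacing_equidistant(self, rect_mask):
        (c,) = extract_contours(rect_mask)
        sp = estimate_spine(c, seed=2)
        positions = [self._arc_position(sp.points, lm) for lm in sp.landmarks]
        spacing = np.diff(positions)
        assert (spacing.max() - spacing.min()) / spacing.mean() < 0.02


class TestHeadDetection:
    def test_dark_blob_marks_head_end(self, single_larva_scene):
        from larvatrack.calibration import compute_histogram, otsu_threshold
        from larvatrack.segmentation import segment_frame

        _, frames, gt = single_larva_scene
        k = otsu_threshold(compute_histogram(frames[0])).k
        hits = tot = 0
        for f in range(0, 100, 5):
            (cont,) = segment_frame(frames[f], k, 70, 800)
            spine = estimate_spine(cont, seed=f)
            end, detected = detect_head(frames[f], cont, spine)
            if not detected:
                continue
            tot += 1
            tip = spine.points[0] if end == "A" else spine.points[-1]
            d_head = np.linalg.norm(tip - gt.midlines[f, 0, 0])
            d_tail = np.linalg.norm(tip - gt.midlines[f, 0, -1])
            hits += d_head < d_tail
        assert tot >= 15
        assert hits == tot

    def test_uniform_body_undetected(self, rect_mask):
        (c,) = extract_contours(rect_mask)
        sp = estimate_spine(c, seed=0)
        frame = np.where(rect_mask, 180, 30).astype(np.uint8)
        end, detected = detect_head(frame, c, sp)
        assert not detected
        assert end == "?"

    def test_equal_blobs_tie_undetected(self, rect_mask):
        (c,) = extract_contours(rect_mask)
        sp = estimate_spine(c, seed=0)
        frame = np.where(rect_mask, 180, 30).astype(np.uint8)
        frame[12:16, 14:18] = 100  # same-size dark blobs at both ends
        frame[12:16, 62:66] = 100
        _, detected = detect_head(frame, c, sp)
        assert not detected


class TestOrientByMotion:
    def _state(self, mask, centroid_shift):
        from larvatrack.geometry import LarvaFrameState

        (c,) = extract_contours(mask)
        c.centroid = c.centroid + centroid_shift
        st = LarvaFrameState(contour=c)
        st.spine = estimate_spine(c, seed=0)
        return st

    def test_translation_decides_head(self, rect_mask):
        history = [self._state(rect_mask, np.array([0.0, -8.0]))]
        current = self._state(rect_mask, np.zeros(2))
        # moving toward increasing column: the end with larger column is ahead
        end = orient_by_motion(history, current)
        lm = current.spine.landmarks
        ahead = "A" if lm[0][1] > lm[6][1] else "B"
        assert end == ahead

    def test_stationary_keeps_previous_orientation(self, rect_mask):
        prev = self._state(rect_mask, np.zeros(2))
        prev.head_end = "B"
        current = self._state(rect_mask, np.zeros(2))
        assert orient_by_motion([prev], current) == "B"

    def test_no_history_unknown(self, rect_mask):
        current = self._state(rect_mask, np.zeros(2))
        assert orient_by_motion([], current) == "?"


class TestBendingAngle:
    def test_collinear_is_zero(self):
        phi, cls = bending_angle([0.0, 2.0], [0.0, 1.0], [0.0, -1.0])
        assert phi == pytest.approx(0.0)
        assert cls is BendClass.NONE

    def test_left_right_angles(self):
        # travelling east (increasing column); up-screen is the animal's left
        tail, mid = np.array([0.0, 0.0]), np.array([0.0, 1.0])
        left_head = np.array([-1.0, 1.0])
        right_head = np.array([1.0, 1.0])
        assert bending_angle(left_head, mid, tail)[0] == pytest.approx(90.0)
        assert bending_angle(right_head, mid, tail)[0] == pytest.approx(-90.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            bending_angle([0, 0], [0, 0], [1, 1])

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50), min_size=6, max_size=6
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_mirror_antisymmetry(self, coords):
        head = np.array(coords[:2])
        mid = np.array(coords[2:4])
        tail = np.array(coords[4:6])
        if (
            np.allclose(head, mid)
            or np.allclose(mid, tail)
        ):
            return
        phi, _ = bending_angle(head, mid, tail)
        mirror = lambda p: np.array([-p[0], p[1]])  # reflect rows
        phi_m, _ = bending_angle(mirror(head), mirror(mid), mirror(tail))
        if abs(abs(phi) - 180.0) < 1e-6:
            assert abs(phi_m) == pytest.approx(180.0, abs=1e-6)
        else:
            assert phi_m == pytest.approx(-phi, abs=1e-9)

    @pytest.mark.parametrize(
        "phi,expected",
        [
            (5, BendClass.NONE),
            (19.9, BendClass.NONE),
            (25, BendClass.SLIGHT),
            (-25, BendClass.SLIGHT),
            (40, BendClass.AVERAGE),
            (-49.9, BendClass.AVERAGE),
            (50, BendClass.STRONG),
            (120, BendClass.STRONG),
        ],
    )
    def test_class_boundaries(self, phi, expected):
        assert classify_bend(phi) is expected
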