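"""Canonical frame and two-landmark similarity registration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retloc import (
    CANVAS_SIZE,
    CanonicalFrame,
    DegenerateLandmarkError,
    LandmarkRecord,
    Laterality,
    Point2D,
    SimilarityTransform,
    compute_colocation_transform,
    warp_mask,
)

from conftest import random_landmark


class TestCanonicalFrame:
    def test_default_geometry(self, frame):
        assert frame.canvas == 1100
        assert abs(frame.disc_right.x - frame.macula_right.x) == pytest.approx(250.0)
        assert frame.macula_right.y - frame.disc_right.y == pytest.approx(25.0)

    def test_left_targets_are_exact_mirror(self, frame):
        assert frame.disc_left.x == (frame.canvas - 1) - frame.disc_right.x
        assert frame.macula_left.x == (frame.canvas - 1) - frame.macula_right.x
        assert frame.disc_left.y == frame.disc_right.y

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CanonicalFrame(
                canvas=1100,
                disc_right=Point2D(600, 537),
                macula_right=Point2D(425, 562),  # separation 175, not 250
            )


class TestSimilarityTransform:
    def test_identity(self):
        t = SimilarityTransform.identity()
        assert t.apply(Point2D(10, 20)) == Point2D(10, 20)

    def test_hand_arithmetic_scale_translate(self):
        t = SimilarityTransform.from_params(0.5, 0.0, (225.0, 287.0))
        p = t.apply(Point2D(400, 550))
        assert (p.x, p.y) == pytest.approx((425.0, 562.0))

    def test_half_turn_rotation(self):
        t = SimilarityTransform.from_params(1.0, math.pi, (0.0, 0.0))
        p = t.apply(Point2D(1, 0))
        assert (p.x, p.y) == pytest.approx((-1.0, 0.0), abs=1e-9)

    def test_double_inversion_is_identity(self):
        t = SimilarityTransform.from_params(1.7, 0.3, (12.0, -4.0))
        tt = t.invert().invert()
        assert tt.a == pytest.approx(t.a, abs=1e-9)
        assert tt.b == pytest.approx(t.b, abs=1e-9)

    def test_round_trip_point(self):
        t = SimilarityTransform.from_params(2.2, -0.8, (31.0, 7.0))
        p = Point2D(123.4, -56.7)
        q = t.invert().apply(t.apply(p))
        assert (q.x, q.y) == pytest.approx((p.x, p.y), abs=1e-6)

    def test_no_reflection_triangle_orientation(self, rng):
        # signed area of a triangle keeps its sign under any similarity
        tri = [Point2D(0, 0), Point2D(10, 0), Point2D(0, 10)]
        for _ in range(50):
            t = SimilarityTransform.from_params(
                float(rng.uniform(0.2, 3.0)),
                float(rng.uniform(-math.pi, math.pi)),
                (float(rng.uniform(-100, 100)), float(rng.uniform(-100, 100))),
            )
            a, b, c = (t.apply(p) for p in tri)
            signed = (b.x - a.x) * (c.y - a.y) - (c.x - a.x) * (b.y - a.y)
            assert signed > 0


class TestColocationTransform:
    def test_landmarks_already_canonical_gives_identity(self, frame):
        lm = LandmarkRecord(
            "id", Point2D(675, 537), Point2D(425, 562), Laterality.RIGHT, 1100, 1100
        )
        t = compute_colocation_transform(lm, frame)
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0)
        assert (t.translation.x, t.translation.y) == pytest.approx((0.0, 0.0))

    def test_known_scale_translation_case(self, frame):
        lm = LandmarkRecord(
            "id", Point2D(900, 500), Point2D(400, 550), Laterality.RIGHT, 1000, 1000
        )
        t = compute_colocation_transform(lm, frame)
        assert t.scale == pytest.approx(0.5)
        assert t.rotation == pytest.approx(0.0)
        assert (t.translation.x, t.translation.y) == pytest.approx((225.0, 287.0))
        d = t.apply(lm.disc)
        m = t.apply(lm.macula)
        assert (d.x, d.y) == pytest.approx((675.0, 537.0), abs=1e-9)
        assert (m.x, m.y) == pytest.approx((425.0, 562.0), abs=1e-9)

    def test_landmark_exactness_random_records(self, frame, rng):
        for i in range(1000):
            lm = random_landmark(rng, f"r{i}")
            t = compute_colocation_transform(lm, frame)
            d_t, m_t = frame.targets(lm.laterality)
            assert t.apply(lm.disc).distance_to(d_t) < 1e-6
            assert t.apply(lm.macula).distance_to(m_t) < 1e-6

    def test_agrees_with_independent_estimator(self, frame, rng):
        # skimage's least-squares similarity estimate from the same two
        # correspondences must coincide with the closed form.
        from skimage.transform import SimilarityTransform as SkSim

        for i in range(20):
            lm = random_landmark(rng, f"x{i}")
            t = compute_colocation_transform(lm, frame)
            d_t, m_t = frame.targets(lm.laterality)
            sk = SkSim()
            src = np.array([[lm.disc.x, lm.disc.y], [lm.macula.x, lm.macula.y]])
            dst = np.array([[d_t.x, d_t.y], [m_t.x, m_t.y]])
            assert sk.estimate(src, dst)
            a_sk = complex(sk.params[0, 0], sk.params[1, 0])
            b_sk = complex(sk.params[0, 2], sk.params[1, 2])
            assert a_sk == pytest.approx(t.a, abs=1e-6)
            assert b_sk == pytest.approx(t.b, abs=1e-6)

    def test_degenerate_landmarks_rejected(self):
        with pytest.raises(DegenerateLandmarkError):
            LandmarkRecord(
                "id", Point2D(400, 400), Point2D(400.5, 400.2),
                Laterality.RIGHT, 1000, 1000,
            )

    def test_unknown_laterality_rejected(self):
        with pytest.raises(ValueError):
            Laterality.parse("both")


class TestWarpMask:
    def test_identity_preserves_canvas_mask(self, rng):
        mask = (rng.random((CANVAS_SIZE, CANVAS_SIZE)) < 0.01).astype(np.uint8)
        out = warp_mask(mask, SimilarityTransform.identity())
        np.testing.assert_array_equal(out, mask)

    def test_single_pixel_lands_on_target(self):
        t = SimilarityTransform.from_params(0.5, 0.0, (225.0, 287.0))
        mask = np.zeros((1000, 1000), np.uint8)
        mask[550, 400] = 1
        out = warp_mask(mask, t)
        assert out[562, 425] == 1
        assert out.sum() == 1

    def test_matches_brute_force_inverse_nn(self, rng):
        t = SimilarityTransform.from_params(1.3, 0.2, (40.0, -10.0))
        mask = (rng.random((80, 90)) < 0.1).astype(np.uint8)
        out = warp_mask(mask, t, canvas=120)
        inv = t.invert()
        expected = np.zeros((120, 120), np.uint8)
        for y in range(120):
            for x in range(120):
                p = inv.apply(Point2D(float(x), float(y)))
                ix, iy = round(p.x), round(p.y)
                if 0 <= ix < 90 and 0 <= iy < 80:
                    expected[y, x] = mask[iy, ix]
        np.testing.assert_array_equal(out, expected)

    @pytest.mark.parametrize("scale", [0.5, 0.8, 1.0, 1.5, 2.0])
    def test_area_scales_with_squared_scale(self, scale, rng):
        mask = np.zeros((300, 300), np.uint8)
        mask[100:200, 120:220] = 1  # 10,000 px blob
        t = SimilarityTransform.from_params(scale, 0.0, (10.0, 10.0))
        out = warp_mask(mask, t, canvas=700)
        ratio = out.sum() / mask.sum()
        assert ratio == pytest.approx(scale**2, rel=0.2)

    def test_round_trip_recovers_foreground(self, rng):
        mask = np.zeros((400, 400), np.uint8)
        mask[150:250, 100:300] = 1
        for scale in (0.8, 1.0, 1.25):
            t = SimilarityTransform.from_params(scale, 0.05, (30.0, 20.0))
            fwd = warp_mask(mask, t, canvas=700)
            back = warp_mask(fwd, t.invert(), canvas=400)
            recovered = (back & mask).sum() / mask.sum()
            assert recovered >= 0.95

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            warp_mask(np.full((5, 5), 3), SimilarityTransform.identity(), canvas=5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.3, 3.0),
    rot=st.floats(-math.pi, math.pi),
    tx=st.floats(-200, 200),
    ty=st.floats(-200, 200),
    px=st.floats(-500, 500),
    py=st.floats(-500, 500),
)
def test_apply_invert_round_trip_property(scale, rot, tx, ty, px, py):
    t = SimilarityTransform.from_params(scale, rot, (tx, ty))
    p = Point2D(px, py)
    q = t.invert().apply(t.apply(p))
    assert q.distance_to(p) < 1e-6
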