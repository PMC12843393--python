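import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from desertveg import (
    InputError,
    ParameterError,
    assemble_features,
    dense_texture,
    glcm_props,
    glcm_window,
    quantize_gray,
)
from desertveg.texture import ANGLES, _OFFSETS

from oracles import naive_glcm, naive_glcm_props


class TestQuantize:
    def test_endpoints_and_midpoint(self):
        img = np.array([[0.0, 1.0], [0.49, 0.51]])
        q = quantize_gray(img, 2)
        assert q.tolist() == [[0, 1], [0, 1]]
        assert quantize_gray(np.array([[1.0]]), 16)[0, 0] == 15

    def test_level_count_bounded(self, rng):
        q = quantize_gray(rng.uniform(0, 1, (20, 20)), 8)
        assert len(np.unique(q)) <= 8 and q.min() >= 0 and q.max() <= 7

    def test_rejects_bad_G(self):
        with pytest.raises(ParameterError):
            quantize_gray(np.zeros((3, 3)), 1)


class TestGlcmWindow:
    def test_constant_window_single_entry(self):
        win = np.full((7, 7), 3)
        for angle in ANGLES:
            g = glcm_window(win, 1, angle, G=8)
            assert g.P[3, 3] == 1.0 and g.P.sum() == 1.0

    def test_checkerboard_horizontal(self):
        win = np.indices((8, 8)).sum(axis=0) % 2
        g = glcm_window(win, 1, 0, G=2)
        assert g.P[0, 1] == 0.5 and g.P[1, 0] == 0.5
        assert g.P[0, 0] == 0.0 and g.P[1, 1] == 0.0

    @pytest.mark.parametrize("angle", ANGLES)
    def test_matches_naive_enumeration(self, angle, rng):
        win = rng.integers(0, 4, (7, 7))
        dr, dc = _OFFSETS[angle]
        ours = glcm_window(win, 1, angle, G=4).P
        ref = naive_glcm(win, dr, dc, 4)
        assert np.array_equal(ours, ref)

    # skimage measures diagonal angles with the row axis flipped relative to
    # the (row-up) convention here, so its pi/4 is this package's 135 degrees
    @pytest.mark.parametrize(
        "angle,ski_angle",
        [(0, 0), (45, 3 * np.pi / 4), (90, np.pi / 2), (135, np.pi / 4)],
    )
    def test_matches_skimage_graycomatrix(self, angle, ski_angle, rng):
        win = rng.integers(0, 5, (7, 7)).astype(np.uint8)
        ours = glcm_window(win, 1, angle, G=5).P
        ref = graycomatrix(win, [1], [ski_angle], levels=5, symmetric=True, normed=True)
        assert np.allclose(ours, ref[:, :, 0, 0], atol=1e-12)

    def test_normalized_and_symmetric(self, rng):
        win = rng.integers(0, 6, (9, 9))
        g = glcm_window(win, 2, 45, G=6)
        assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(g.P, g.P.T)

    def test_too_small_window_rejected(self):
        from desertveg import DegenerateInputError

        with pytest.raises(DegenerateInputError):
            glcm_window(np.zeros((1, 1), dtype=int), 1, 0, G=2)


class TestGlcmProps:
    def test_constant_window_degenerate_values(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = glcm_props(P)
        assert (f.contrast, f.homogeneity, f.energy, f.correlation) == (0, 1, 1, 1)

    def test_checkerboard_values(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_props(P)
        assert f.contrast == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.energy == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)

    def test_matches_summation_oracle(self, rng):
        P = rng.uniform(0, 1, (4, 4))
        P /= P.sum()
        f = glcm_props(P)
        c, h, e, r = naive_glcm_props(P)
        assert f.contrast == pytest.approx(c, abs=1e-12)
        assert f.homogeneity == pytest.approx(h, abs=1e-12)
        assert f.energy == pytest.approx(e, abs=1e-12)
        assert f.correlation == pytest.approx(r, abs=1e-12)

    def test_matches_skimage_where_definitions_agree(self, rng):
        win = rng.integers(0, 5, (7, 7)).astype(np.uint8)
        P = graycomatrix(win, [1], [0], levels=5, symmetric=True, normed=True)
        f = glcm_props(P[:, :, 0, 0])
        assert f.contrast == pytest.approx(graycoprops(P, "contrast")[0, 0], abs=1e-10)
        assert f.energy == pytest.approx(graycoprops(P, "energy")[0, 0] ** 2, abs=1e-10)
        assert f.correlation == pytest.approx(graycoprops(P, "correlation")[0, 0], abs=1e-10)

    def test_bounds_on_random_instances(self, rng):
        for _ in range(20):
            P = rng.uniform(0, 1, (6, 6))
            P /= P.sum()
            f = glcm_props(P)
            assert f.contrast >= 0
            assert 0 < f.homogeneity <= 1
            assert 0 < f.energy <= 1
            assert -1 - 1e-12 <= f.correlation <= 1 + 1e-12


class TestDenseTexture:
    def test_constant_image(self):
        t = dense_texture(np.full((10, 10), 0.5), 7, 1, 8)
        assert np.all(t[..., 0] == 0)  # contrast
        assert np.all(t[..., 1] == 1)  # homogeneity
        assert np.all(t[..., 2] == 1)  # energy
        assert np.all(t[..., 3] == 1)  # correlation (degenerate convention)

    def test_matches_per_pixel_recomputation(self, rng):
        gray = rng.uniform(0, 1, (24, 24))
        G = 8
        dense = dense_texture(gray, 7, 1, G)
        lev = quantize_gray(gray, G)
        pad = np.pad(lev, 3, mode="symmetric")
        for y in range(0, 24, 5):
            for x in range(0, 24, 5):
                win = pad[y : y + 7, x : x + 7]
                ref = np.mean(
                    [glcm_props(glcm_window(win, 1, a, G=G)).as_array() for a in ANGLES],
                    axis=0,
                )
                assert np.allclose(dense[y, x], ref, atol=1e-10)

    def test_stripes_orientation_sensitivity(self):
        # vertical stripes: horizontal pairs alternate, vertical pairs agree
        gray = np.tile(np.array([0.0, 1.0] * 8), (16, 1))
        t0 = dense_texture(gray, 7, 1, 2, angles=(0,))
        t90 = dense_texture(gray, 7, 1, 2, angles=(90,))
        assert t0[8, 8, 0] > t90[8, 8, 0]
        assert t90[8, 8, 0] == 0.0

    def test_rotation_consistency_on_interior(self, rng):
        # orientation-averaged features of a 90-degree-rotated image equal
        # the rotated feature map away from borders
        gray = rng.uniform(0, 1, (20, 20))
        t = dense_texture(gray, 5, 1, 6)
        tr = dense_texture(np.rot90(gray), 5, 1, 6)
        inner = slice(4, -4)
        assert np.allclose(np.rot90(t, axes=(0, 1))[inner, inner], tr[inner, inner], atol=1e-10)

    def test_rejects_even_window(self):
        with pytest.raises(ParameterError):
            dense_texture(np.zeros((10, 10)), 6, 1, 8)


class TestAssemble:
    def test_channel_order_and_hue_scaling(self):
        hsv = np.array([[[120.0, 1.0, 0.5]]])
        tex = np.array([[[0.0, 1.0, 1.0, 1.0]]])
        fs = assemble_features(hsv, tex)
        assert fs.shape == (1, 1, 7)
        assert np.allclose(fs[0, 0], [1 / 3, 1.0, 0.5, 0.0, 1.0, 1.0, 1.0])

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(InputError):
            assemble_features(np.zeros((2, 2, 3)), np.zeros((3, 3, 4)))
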