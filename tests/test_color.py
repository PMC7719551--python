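"""Color conversion, centroids, dichromatism geometry, palette, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from PIL import Image

import dichroma as dc
from dichroma.color import (
    PixelSample,
    _arbitrary_insertion,
    _tour_length,
    _two_opt,
    order_palette,
)

finite_lab = st.tuples(
    st.floats(0, 100), st.floats(-120, 120), st.floats(-120, 120)
)


class TestSrgbToLab:
    @pytest.mark.parametrize(
        "rgb, expected, tol",
        [
            ((255, 255, 255), (100.0, 0.0, 0.0), 1e-9),  # white reference
            ((0, 0, 0), (0.0, 0.0, 0.0), 1e-9),
            # CIELAB of sRGB red under D65, from the standard formulas
            ((255, 0, 0), (53.2408, 80.0925, 67.2032), 5e-3),
        ],
    )
    def test_reference_colors(self, rgb, expected, tol):
        assert np.allclose(dc.srgb_to_lab(rgb), expected, atol=tol)

    def test_grays_on_neutral_axis(self):
        grays = np.stack([np.arange(256)] * 3, axis=-1)
        lab = dc.srgb_to_lab(grays)
        assert np.abs(lab[:, 1:]).max() < 1e-6
        assert np.all(np.diff(lab[:, 0]) > 0)  # lightness monotone in gray level

    def test_agrees_with_skimage(self):
        from skimage.color import rgb2lab

        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, size=(500, 3))
        ours = dc.srgb_to_lab(rgb)
        theirs = rgb2lab(rgb / 255.0)
        assert np.abs(ours - theirs).max() < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dc.srgb_to_lab([300, 0, 0])
        with pytest.raises(ValueError):
            dc.srgb_to_lab([-1, 0, 0])


class TestCentroidAndDichromatism:
    def test_single_pixel_identity(self):
        s = PixelSample("sp", "male", [(50.0, 10.0, -10.0)])
        c = dc.centroid(s)
        assert (c.L, c.a, c.b) == (50.0, 10.0, -10.0)

    def test_midpoint(self):
        s = PixelSample("sp", "male", [(0, 0, 0), (100, 0, 0)])
        assert dc.centroid(s).L == 50.0

    def test_centroid_inside_pixel_bounding_box(self):
        rng = np.random.default_rng(1)
        pix = rng.uniform(-50, 50, size=(200, 3))
        c = dc.centroid(PixelSample("sp", "f", pix)).as_array()
        assert np.all(c >= pix.min(axis=0)) and np.all(c <= pix.max(axis=0))

    def test_monochromatic_zero(self):
        rec = dc.dichromatism((50, 5, 5), (50, 5, 5))
        assert rec.D_mag == 0.0

    def test_3_4_5(self):
        rec = dc.dichromatism((3, 4, 0), (0, 0, 0))
        assert rec.D_mag == pytest.approx(5.0)
        assert np.allclose(rec.D_vec, [3, 4, 0])

    def test_swap_symmetry(self):
        a, b = (10.0, 2.0, -3.0), (40.0, -7.0, 9.0)
        r1, r2 = dc.dichromatism(a, b), dc.dichromatism(b, a)
        assert r1.D_mag == r2.D_mag
        assert np.allclose(r1.D_vec, -r2.D_vec)

    @given(finite_lab, finite_lab, finite_lab)
    def test_triangle_inequality(self, x, y, z):
        dxy = dc.dichromatism(x, y).D_mag
        dyz = dc.dichromatism(y, z).D_mag
        dxz = dc.dichromatism(x, z).D_mag
        assert dxz <= dxy + dyz + 1e-9

    def test_rotation_invariance_of_distance(self):
        # rigid rotation in the (a, b) chroma plane preserves centroid distance
        rng = np.random.default_rng(2)
        cm, cf = rng.uniform(-40, 40, 3), rng.uniform(-40, 40, 3)
        th = 1.234
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
        d0 = dc.dichromatism(cm, cf).D_mag
        d1 = dc.dichromatism(R @ cm, R @ cf).D_mag
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestSamplePixels:
    def _image(self, colors, counts):
        px = np.repeat(np.asarray(colors, np.uint8), counts, axis=0)
        h = px.shape[0]
        return Image.fromarray(px.reshape(h, 1, 3), "RGB")

    def test_uniform_image_all_identical(self):
        img = self._image([(10, 200, 30)], [64])
        s = dc.sample_pixels(img, 100, seed=0)
        assert np.allclose(s.pixels, s.pixels[0])
        assert s.n == 100  # sampled with replacement from 64 pixels

    def test_seed_determinism(self):
        img = self._image([(10, 200, 30), (200, 10, 30)], [40, 24])
        s1 = dc.sample_pixels(img, 50, seed=42)
        s2 = dc.sample_pixels(img, 50, seed=42)
        assert np.array_equal(s1.pixels, s2.pixels)

    def test_two_color_fractions_match_binomial(self):
        img = self._image([(255, 0, 0), (0, 0, 255)], [300, 100])  # 3:1
        s = dc.sample_pixels(img, 50_000, seed=3)
        red = dc.srgb_to_lab((255, 0, 0))
        frac = np.isclose(s.pixels, red, atol=1e-9).all(axis=1).mean()
        # 4 sigma binomial band around 0.75 at n = 50,000
        assert abs(frac - 0.75) < 4 * np.sqrt(0.75 * 0.25 / 50_000)

    def test_alpha_mask_and_background_keying(self):
        arr = np.zeros((4, 4, 4), np.uint8)
        arr[..., :3] = (255, 255, 255)
        arr[1, 1] = (10, 20, 30, 255)  # only opaque pixel
        s = dc.sample_pixels(Image.fromarray(arr, "RGBA"), 10, seed=0)
        assert np.allclose(s.pixels, dc.srgb_to_lab((10, 20, 30)))
        rgb = np.full((3, 3, 3), 200, np.uint8)
        rgb[0, 0] = (1, 2, 3)
        s2 = dc.sample_pixels(Image.fromarray(rgb, "RGB"), 5, seed=0,
                              background=(200, 200, 200))
        assert np.allclose(s2.pixels, dc.srgb_to_lab((1, 2, 3)))

    def test_empty_foreground_errors(self):
        arr = np.zeros((4, 4, 4), np.uint8)  # fully transparent
        with pytest.raises(ValueError, match="foreground"):
            dc.sample_pixels(Image.fromarray(arr, "RGBA"), 10, seed=0)


class TestPalette:
    def test_k1_fractions(self):
        samples = {"x": [(0, 0, 0), (1, 1, 1)], "y": [(5, 5, 5)]}
        prof = dc.palette_profile(samples, k=1, seed=0)
        assert np.allclose(prof.fractions.to_numpy(), 1.0)

    def test_separable_colors_recovered(self):
        a, b = np.array([80.0, 0.0, 0.0]), np.array([10.0, 50.0, -50.0])
        rng = np.random.default_rng(0)
        samples = {
            "s1": a + rng.normal(0, 0.01, (50, 3)),
            "s2": b + rng.normal(0, 0.01, (50, 3)),
        }
        prof = dc.palette_profile(samples, k=2, seed=1)
        got = prof.centers[np.argsort(prof.centers[:, 0])]
        assert np.allclose(got, np.vstack([b, a]), atol=0.05)
        assert np.allclose(prof.fractions.sum(axis=1), 1.0)

    def test_k_out_of_range(self):
        samples = {"x": [(0, 0, 0), (0, 0, 0), (1, 1, 1)]}
        with pytest.raises(ValueError):
            dc.palette_profile(samples, k=0)
        with pytest.raises(ValueError):
            dc.palette_profile(samples, k=3)  # only 2 distinct colors

    def test_two_opt_never_worsens_tour(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, size=(20, 3))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ins = _arbitrary_insertion(dist)
        improved = _two_opt(dist, list(ins))
        assert _tour_length(pts, improved) <= _tour_length(pts, ins) + 1e-9

    def test_order_is_permutation(self):
        rng = np.random.default_rng(6)
        order = order_palette(rng.uniform(0, 100, size=(12, 3)))
        assert sorted(order) == list(range(12))


class TestStructureCorrelation:
    def _set(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(-30, 60, (8, 3)), columns=["L", "a", "b"],
            index=[f"s{i}" for i in range(8)],
        )

    def test_identity(self):
        A = self._set()
        res = dc.structure_correlation(A, A)
        assert np.allclose(res["r"], 1.0) and np.allclose(res["slope"], 1.0)

    def test_linear_scaling(self):
        A = self._set(1)
        res = dc.structure_correlation(A, 0.5 * A)
        assert np.allclose(res["r"], 1.0) and np.allclose(res["slope"], 0.5)

    def test_mismatched_ids_error(self):
        A = self._set(2)
        B = A.copy()
        B.index = [f"t{i}" for i in range(8)]
        with pytest.raises(ValueError, match="identifiers"):
            dc.structure_correlation(A, B)
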