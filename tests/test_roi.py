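"""Geometry of rosette ROIs: rasterization, erosion/dilation in µm, morphometrics."""

import numpy as np
import pytest

from organoidquant.roi import (
    BoundaryPolyline,
    GeometryError,
    DegenerateRegionError,
    PixelGrid,
    RosetteROI,
    build_body_mask,
    build_ribbon_mask,
    build_rosette_roi,
    ellipse_polyline,
    rasterize_polygon,
    rosette_morphometrics,
)

from _oracles import brute_body_mask, brute_ribbon_mask, star_polygon


def square(side_um, origin=(0.0, 0.0)):
    x0, y0 = origin
    return BoundaryPolyline(
        np.array([[x0, y0], [x0 + side_um, y0], [x0 + side_um, y0 + side_um], [x0, y0 + side_um]])
    )


class TestRasterizePolygon:
    def test_axis_aligned_square_tiles_exactly(self):
        grid = PixelGrid(20, 20, 1.0)
        mask = rasterize_polygon(square(10, origin=(5, 5)), grid)
        assert mask.sum() == 100

    def test_circle_area_within_one_percent(self):
        grid = PixelGrid(240, 240, 0.1)
        circle = ellipse_polyline((12, 12), (10, 10), n_vertices=256)
        area = rasterize_polygon(circle, grid).sum() * 0.1**2
        assert area == pytest.approx(np.pi * 100, rel=0.01)

    @pytest.mark.parametrize(
        "vertices, closed",
        [
            (np.array([[0.0, 0.0], [5.0, 5.0]]), True),  # 2 vertices
            (np.array([[0, 0], [5, 0], [5, 5], [0, 5]]), False),  # open
            (np.array([[0, 0], [5, 5], [5, 0], [0, 5]]), True),  # bowtie
        ],
    )
    def test_invalid_polygons_raise(self, vertices, closed):
        grid = PixelGrid(10, 10, 1.0)
        with pytest.raises(GeometryError):
            rasterize_polygon(BoundaryPolyline(np.asarray(vertices, float), closed=closed), grid)


def concentric(radius_outer, radius_inner, pixel_size, pad=5.0):
    c = radius_outer + pad
    size = int(round(2 * c / pixel_size))
    grid = PixelGrid(size, size, pixel_size)
    outer = ellipse_polyline((c, c), (radius_outer, radius_outer), n_vertices=512)
    inner = ellipse_polyline((c, c), (radius_inner, radius_inner), n_vertices=512)
    return outer, inner, grid


class TestBodyMask:
    def test_analytic_annulus_area_after_erosion(self):
        outer, inner, grid = concentric(30, 10, 0.2)
        body = build_body_mask(outer, inner, grid).body_mask
        expected = np.pi * (28.2**2 - 11.8**2)
        assert body.sum() * 0.2**2 == pytest.approx(expected, rel=0.01)

    def test_zero_erosion_is_the_annulus(self):
        outer, inner, grid = concentric(20, 8, 0.4)
        annulus = rasterize_polygon(outer, grid) & ~rasterize_polygon(inner, grid)
        body = build_body_mask(outer, inner, grid, erosion_um=0).body_mask
        assert np.array_equal(body, annulus)

    def test_inner_outside_outer_raises(self):
        grid = PixelGrid(100, 100, 0.5)
        outer = ellipse_polyline((25, 25), (10, 10))
        inner = ellipse_polyline((40, 40), (5, 5))
        with pytest.raises(GeometryError):
            build_body_mask(outer, inner, grid)

    def test_empty_body_warns(self):
        outer, inner, grid = concentric(6, 4, 0.5)
        with pytest.warns(UserWarning, match="empty"):
            roi = build_body_mask(outer, inner, grid, erosion_um=5.0)
        assert not roi.body_mask.any()

    def test_otsu_refinement_drops_exactly_the_dim_pixels(self):
        outer, inner, grid = concentric(20, 6, 0.5)
        plain = build_body_mask(outer, inner, grid).body_mask
        img = np.full(grid.shape, 200.0)
        dim = rasterize_polygon(ellipse_polyline((26 + 12, 26), (4, 4)), grid)
        img[dim] = 20.0
        refined = build_body_mask(outer, inner, grid, channel=img, refine=True)
        assert 20.0 < refined.otsu_threshold <= 200.0
        assert np.array_equal(refined.body_mask, plain & ~dim)

    def test_erosion_monotonically_shrinks_body(self):
        outer, inner, grid = concentric(20, 8, 0.4)
        masks = [build_body_mask(outer, inner, grid, erosion_um=e).body_mask for e in (0, 1, 2, 3.5)]
        for bigger, smaller in zip(masks, masks[1:]):
            assert np.array_equal(smaller & bigger, smaller)  # nested
            assert smaller.sum() < bigger.sum()


class TestRibbonMask:
    def test_analytic_band_area(self):
        _, inner, grid = concentric(30, 20, 0.2)
        ribbon = build_ribbon_mask(inner, grid).ribbon_mask
        expected = np.pi * (21.8**2 - 18.2**2)  # 452.39 µm²
        assert ribbon.sum() * 0.2**2 == pytest.approx(expected, rel=0.01)

    def test_zero_dilation_is_the_rasterized_polyline(self):
        _, inner, grid = concentric(20, 10, 0.5)
        ribbon = build_ribbon_mask(inner, grid, dilation_um=0).ribbon_mask
        # a thin connected loop: roughly the circle's perimeter in pixels
        assert 0 < ribbon.sum() < 4 * 2 * np.pi * 10 / 0.5

    def test_dilation_monotonically_grows_ribbon(self):
        _, inner, grid = concentric(20, 8, 0.4)
        masks = [build_ribbon_mask(inner, grid, dilation_um=d).ribbon_mask for d in (0.5, 1.8, 3.0)]
        for smaller, bigger in zip(masks, masks[1:]):
            assert np.array_equal(smaller & bigger, smaller)

    def test_body_and_ribbon_disjoint_at_shared_margin(self):
        outer, inner, grid = concentric(25, 9, 0.3)
        roi = build_rosette_roi(outer, inner, grid)
        assert not (roi.body_mask & roi.ribbon_mask).any()


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_masks_match_brute_force_pixel_for_pixel(self, seed):
        rng = np.random.default_rng(seed)
        grid = PixelGrid(96, 96, 0.5)
        outer_v = star_polygon(rng, (24, 24), 16.0, wobble=0.2)
        inner_v = star_polygon(rng, (24, 24), 5.0, wobble=0.15)
        outer, inner = BoundaryPolyline(outer_v), BoundaryPolyline(inner_v)
        body = build_body_mask(outer, inner, grid).body_mask
        ribbon = build_ribbon_mask(inner, grid).ribbon_mask
        assert np.array_equal(body, brute_body_mask(outer_v, inner_v, grid, 1.8))
        assert np.array_equal(ribbon, brute_ribbon_mask(inner_v, grid, 1.8))


def resolution_errors():
    """Relative body-area error at successively finer pixel sizes."""
    errors = []
    expected = np.pi * (28.2**2 - 11.8**2)
    for px in (0.4, 0.2, 0.1):
        outer, inner, grid = concentric(30, 10, px)
        area = build_body_mask(outer, inner, grid).body_mask.sum() * px**2
        errors.append(abs(area / expected - 1))
    return errors


def test_area_error_shrinks_with_resolution():
    errors = resolution_errors()
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 0.01


class TestMorphometrics:
    def _roi_from_mask(self, mask, grid):
        return RosetteROI(grid=grid, body_mask=mask, ribbon_mask=np.zeros_like(mask))

    def test_circle_aspect_ratio_is_one(self):
        grid = PixelGrid(220, 220, 0.2)
        mask = rasterize_polygon(ellipse_polyline((22, 22), (18, 18)), grid)
        _, aspect = rosette_morphometrics(self._roi_from_mask(mask, grid), grid)
        assert aspect == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("angle", np.linspace(0, np.pi, 8, endpoint=False))
    def test_ellipse_aspect_two_and_rotation_invariant(self, angle):
        grid = PixelGrid(460, 460, 0.2)
        mask = rasterize_polygon(ellipse_polyline((46, 46), (40, 20), rotation_rad=angle), grid)
        _, aspect = rosette_morphometrics(self._roi_from_mask(mask, grid), grid)
        assert aspect == pytest.approx(2.0, rel=0.02)

    def test_area_is_sum_of_body_and_ribbon_pixels(self):
        outer, inner, grid = concentric(30, 10, 0.2)
        roi = build_rosette_roi(outer, inner, grid)
        area, aspect = rosette_morphometrics(roi, grid)
        expected = np.pi * (28.2**2 - 11.8**2) + np.pi * (11.8**2 - 8.2**2)
        assert area == pytest.approx(expected, rel=0.01)
        assert aspect >= 1.0

    def test_empty_union_raises(self):
        grid = PixelGrid(10, 10, 1.0)
        empty = np.zeros(grid.shape, dtype=bool)
        with pytest.raises(DegenerateRegionError):
            rosette_morphometrics(self._roi_from_mask(empty, grid), grid)
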