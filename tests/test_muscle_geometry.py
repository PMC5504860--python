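"""Geometry tests: rasterization, medial axis, width profile, morphology.

Analytic oracles: shoelace areas, the centerline of a rectangle (skeleton
ends retract by about the half-width), and the mid-radius arc of a
quarter annulus.
"""

import math

import numpy as np
import pytest

from myospat import muscle_geometry as mg
from myospat.muscle_geometry import GeometryError


def rect_polygon(w, h, x0=-0.5, y0=-0.5):
    return np.array(
        [[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]], dtype=float
    )


def rect_mask(shape=(40, 220), y0=10, y1=30, x0=10, x1=210):
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


def quarter_annulus_mask(r_in=90.0, r_out=110.0, size=130):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rr = np.hypot(xx, yy)
    return (rr >= r_in) & (rr <= r_out)


class TestRasterize:
    def test_axis_aligned_rectangle_pixel_count(self):
        mask = mg.rasterize(rect_polygon(100, 20), (64, 128))
        assert mask.sum() == 100 * 20

    def test_triangle_area_matches_shoelace_up_to_boundary(self):
        # pixel-centre counting can deviate from the continuous area by up
        # to about half the perimeter (boundary pixels)
        poly = np.array([[0.0, 0.0], [60.0, 0.0], [0.0, 60.0]])
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        perimeter = np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0), axis=1).sum()
        mask = mg.rasterize(poly, (70, 70))
        assert abs(mask.sum() - shoelace) <= perimeter / 2 + 3

    def test_polygon_outside_image_gives_empty_mask(self):
        poly = rect_polygon(10, 10, x0=500.0, y0=500.0)
        assert not mg.rasterize(poly, (64, 64)).any()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeometryError):
            mg.rasterize(np.array([[0.0, 0.0], [5.0, 5.0]]), (16, 16))
        with pytest.raises(GeometryError):
            mg.rasterize(np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 10.0]]), (16, 16))


class TestMedialAxis:
    def test_rectangle_centerline_without_extension(self):
        # skeleton ends retract by ~half-width: expect the segment x in [10, 190]
        axis, arc = mg.medial_axis_polyline(rect_mask(), extend_to_boundary=False)
        assert arc[-1] == pytest.approx(180.0, rel=0.05)
        assert np.all(np.abs(axis[:, 1] - 19.5) < 3.0)  # y stays near the midline

    def test_rectangle_centerline_extended_spans_pole_to_pole(self):
        axis, arc = mg.medial_axis_polyline(rect_mask(), extend_to_boundary=True)
        assert arc[-1] == pytest.approx(200.0, rel=0.03)

    def test_quarter_annulus_arc_length(self):
        axis, arc = mg.medial_axis_polyline(quarter_annulus_mask())
        assert arc[-1] == pytest.approx(100.0 * math.pi / 2, rel=0.05)

    def test_orientation_starts_at_smaller_y(self):
        mask = np.zeros((220, 40), dtype=bool)
        mask[10:210, 10:30] = True  # vertical muscle
        axis, _ = mg.medial_axis_polyline(mask)
        assert axis[0, 1] < axis[-1, 1]

    def test_non_elongated_blob_rejected(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        disk = (xx - 32) ** 2 + (yy - 32) ** 2 <= 20**2
        with pytest.raises(GeometryError, match="elongation"):
            mg.medial_axis_polyline(disk)

    def test_multiple_components_rejected_with_count(self):
        mask = rect_mask()
        mask[5:8, 5:8] = True  # second component
        with pytest.raises(GeometryError, match="2"):
            mg.medial_axis_polyline(mask)

    def test_points_inside_mask(self):
        mask = rect_mask()
        axis, _ = mg.medial_axis_polyline(mask, extend_to_boundary=True)
        iy = np.clip(np.round(axis[:, 1]).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip(np.round(axis[:, 0]).astype(int), 0, mask.shape[1] - 1)
        assert mask[iy, ix].mean() > 0.99

    def test_rotation_equivariance_90_degrees(self):
        mask = rect_mask()
        axis, arc = mg.medial_axis_polyline(mask)
        rot_axis, rot_arc = mg.medial_axis_polyline(np.rot90(mask))
        assert rot_arc[-1] == pytest.approx(arc[-1], rel=0.02)
        w = mg.width_profile(mask, axis, arc, 20, 1.25)
        w_rot = mg.width_profile(np.rot90(mask), rot_axis, rot_arc, 20, 1.25)
        assert np.mean(w_rot) == pytest.approx(np.mean(w), rel=0.02)


class TestWidthProfile:
    def test_constant_width_rectangle(self):
        mask = rect_mask()
        axis, arc = mg.medial_axis_polyline(mask, extend_to_boundary=False)
        widths = mg.width_profile(mask, axis, arc, 30, 1.25)
        np.testing.assert_allclose(widths, 20 * 1.25, atol=1.25)

    def test_tapered_mask_gives_monotone_widths(self):
        mask = np.zeros((60, 220), dtype=bool)
        for x in range(10, 210):
            half = 15 - 10 * (x - 10) / 200.0  # 30 px wide tapering to 10
            mask[int(round(30 - half)):int(round(30 + half)) + 1, x] = True
        axis, arc = mg.medial_axis_polyline(mask, extend_to_boundary=False)
        widths = mg.width_profile(mask, axis, arc, 12, 1.0)
        inner = widths[1:-1]  # ends are affected by skeleton retraction
        assert np.all(np.diff(inner) <= 1.0)  # decreasing within 1 px jitter
        assert inner[0] > inner[-1] + 10

    def test_u2_samples_both_ends(self):
        mask = rect_mask()
        axis, arc = mg.medial_axis_polyline(mask)
        widths = mg.width_profile(mask, axis, arc, 2, 1.25)
        assert len(widths) == 2

    def test_u_must_be_at_least_2(self):
        mask = rect_mask()
        axis, arc = mg.medial_axis_polyline(mask)
        with pytest.raises(ValueError):
            mg.width_profile(mask, axis, arc, 1, 1.25)


class TestMorphology:
    def test_rectangle_centroid_by_symmetry(self):
        mask = np.zeros((64, 128), dtype=bool)
        mask[0:20, 0:100] = True
        centroid, area = mg.morphology(mask, 1.25)
        assert centroid == pytest.approx((49.5, 9.5))

    def test_area_scaling(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask.flat[:1000] = True
        _, area = mg.morphology(mask, 1.25)
        assert area == pytest.approx(1562.5)

    def test_translation_equivariance(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:15, 10:30] = True
        c1, _ = mg.morphology(mask, 1.0)
        c2, _ = mg.morphology(np.roll(np.roll(mask, 7, axis=0), 3, axis=1), 1.0)
        assert c2 == pytest.approx((c1[0] + 3, c1[1] + 7))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mg.morphology(np.zeros((8, 8), dtype=bool), 1.0)


def test_capsule_length_recovery(small_fixture):
    """For capsules built from a known centerline, the recovered pole-to-pole
    length matches centerline + two cap radii within 5%."""
    cfg, movie, boundaries, gt = small_fixture
    geom = mg.from_polygon(boundaries[0], movie.shape, cfg.pixel_size_um)
    expected = cfg.centerline_length_px + 2 * cfg.half_width_px
    assert geom.length_px == pytest.approx(expected, rel=0.05)
    np.testing.assert_allclose(
        geom.width_profile_um[len(geom.width_profile_um) // 2],
        2 * cfg.half_width_px * cfg.pixel_size_um,
        atol=1.5 * cfg.pixel_size_um,
    )
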