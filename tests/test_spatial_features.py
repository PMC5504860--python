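"""Spatial-feature tests: straightening geometry and the NSD / L_n /
NM_lon / M_lat / NM_lat closed forms."""

import math

import numpy as np
import pytest

from myospat import muscle_geometry as mg
from myospat.muscle_geometry import MuscleGeometry
from myospat.nuclear_segmentation import Blob, NucleusBlobSet
from myospat.spatial_features import (
    FeatureParams,
    feature_record,
    lateral_spread,
    longitudinal_spread,
    nsd,
    straighten,
)


def vertical_geometry(height=300, width=40, px=1.25):
    """A straight vertical rectangle muscle with an analytic medial axis."""
    mask = np.zeros((height + 20, width + 20), dtype=bool)
    mask[10 : 10 + height, 10 : 10 + width] = True
    n = height + 1
    axis = np.column_stack([np.full(n, 10 + width / 2 - 0.5), 10.0 + np.arange(n)])
    arc = np.arange(n, dtype=float)
    widths = np.full(50, width * px)
    return MuscleGeometry(
        mask, axis, arc, px, widths, (10 + width / 2, 10 + height / 2),
        float(mask.sum()) * px * px,
    )


def disk_blob(label, cx, cy, r=6):
    yy, xx = np.mgrid[
        int(cy) - r : int(cy) + r + 1, int(cx) - r : int(cx) + r + 1
    ]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    pix = np.column_stack([yy[inside], xx[inside]])
    return Blob(label, (float(cx), float(cy)), len(pix), pix)


def frame_of(geom, *blobs):
    return NucleusBlobSet(0, np.zeros(geom.mask.shape, dtype=np.int32), list(blobs))


class TestStraighten:
    def test_vertical_muscle_is_identity_geometry(self):
        geom = vertical_geometry()
        blob = disk_blob(1, geom.medial_axis[0, 0] + 5, 10 + 40)
        sf = straighten(frame_of(geom, blob), geom)
        n = sf.nuclei[0]
        assert n.dx == pytest.approx(5.0, abs=1e-6)
        assert n.dy == pytest.approx(40.0, abs=1e-6)
        assert n.alpha == pytest.approx(0.0, abs=1e-6)
        assert n.centroid[0] == pytest.approx(sf.X + 5)
        assert n.centroid[1] == pytest.approx(40.0)

    def test_mirrored_nucleus_flips_sign(self):
        geom = vertical_geometry()
        cx = geom.medial_axis[0, 0]
        left = disk_blob(1, cx - 5, 50)
        right = disk_blob(2, cx + 5, 50)
        sf = straighten(frame_of(geom, left, right), geom)
        assert sf.nuclei[0].dx == pytest.approx(-5.0, abs=1e-6)
        assert sf.nuclei[1].dx == pytest.approx(+5.0, abs=1e-6)

    def test_quarter_arc_analytic_dx_dy(self):
        """On a quarter-circle capsule, recovered (dx, dy) match the arc
        parametrization within 1 px."""
        from shapely.geometry import LineString

        R, cx0, cy0 = 100.0, 20.0, 120.0
        theta = np.linspace(0, math.pi / 2, 200)
        line = np.column_stack(
            [cx0 + R * np.cos(theta), cy0 - R * np.sin(theta)]
        )  # from (120,120) to (20,20)
        poly = np.asarray(LineString(line).buffer(15, cap_style="round").exterior.coords)
        geom = mg.from_polygon(poly, (160, 160), 1.25)
        # nucleus on the centerline, 35 px of arc from the (20,20)-side end
        phi = 35.0 / R
        gx = cx0 + R * math.sin(phi)
        gy = cy0 - R * math.cos(phi)
        sf = straighten(frame_of(geom, disk_blob(1, gx, gy, r=3)), geom)
        n = sf.nuclei[0]
        assert abs(n.dx) <= 1.0                    # on the axis
        assert n.dy == pytest.approx(35.0 + 15.0, abs=1.5)  # cap adds 15 px
        # alpha equals the tangent angle at the foot point
        assert n.alpha == pytest.approx(math.pi / 2 - phi, abs=0.1)

    def test_area_preserved_exactly(self):
        geom = vertical_geometry()
        blob = disk_blob(1, geom.medial_axis[0, 0] + 7, 80)
        sf = straighten(frame_of(geom, blob), geom)
        assert len(sf.nuclei[0].points) == blob.area_px

    def test_x_offset_keeps_coordinates_nonnegative(self):
        geom = vertical_geometry()
        blob = disk_blob(1, geom.medial_axis[0, 0] - 18, 80)
        sf = straighten(frame_of(geom, blob), geom)
        assert sf.nuclei[0].points[:, 0].min() >= 0


class TestNsd:
    def test_hull_covering_cell_gives_one(self):
        geom = vertical_geometry(height=100, width=30)
        ys, xs = np.nonzero(geom.mask)
        pix = np.column_stack([ys, xs])
        blob = Blob(1, (float(xs.mean()), float(ys.mean())), len(pix), pix)
        value = nsd(straighten(frame_of(geom, blob), geom), geom)
        assert value == pytest.approx(1.0, rel=0.07)

    def test_half_cell_hull_gives_half(self):
        geom = vertical_geometry(height=200, width=30)
        mask = np.zeros_like(geom.mask)
        mask[10:110, 10:40] = True  # top half of the muscle rectangle
        ys, xs = np.nonzero(mask)
        pix = np.column_stack([ys, xs])
        blob = Blob(1, (float(xs.mean()), float(ys.mean())), len(pix), pix)
        value = nsd(straighten(frame_of(geom, blob), geom), geom)
        assert value == pytest.approx(0.5, rel=0.07)

    def test_larger_cell_halves_nsd(self):
        small = vertical_geometry(height=100, width=30)
        ys, xs = np.nonzero(small.mask)
        pix = np.column_stack([ys, xs])
        blob = Blob(1, (float(xs.mean()), float(ys.mean())), len(pix), pix)
        v_small = nsd(straighten(frame_of(small, blob), small), small)
        big = vertical_geometry(height=200, width=30)  # same hull, double area
        v_big = nsd(straighten(frame_of(big, blob), big), big)
        assert v_big == pytest.approx(v_small / 2, rel=0.02)

    def test_degenerate_point_sets_give_zero(self):
        geom = vertical_geometry()
        pix = np.array([[50, 25], [51, 25], [52, 25]])  # collinear
        blob = Blob(1, (25.0, 51.0), 3, pix)
        assert nsd(straighten(frame_of(geom, blob), geom), geom) == 0.0


class TestLongitudinal:
    def test_extent_from_pixel_span(self):
        geom = vertical_geometry()
        cx = geom.medial_axis[0, 0]
        pix = np.array([[10 + 40, int(cx)], [10 + 200, int(cx)]])
        blob = Blob(1, (cx, 10 + 120.0), 2, pix)
        ln, nm = longitudinal_spread(straighten(frame_of(geom, blob), geom), geom)
        assert ln == pytest.approx(160 * 1.25)  # (200-40) px
        assert nm == pytest.approx(160 * 1.25 / geom.length_um)

    def test_single_pixel_nucleus_has_zero_spread(self):
        geom = vertical_geometry()
        pix = np.array([[60, 29]])
        blob = Blob(1, (29.0, 60.0), 1, pix)
        ln, nm = longitudinal_spread(straighten(frame_of(geom, blob), geom), geom)
        assert ln == 0.0 and nm == 0.0

    def test_ln_never_exceeds_lc(self, scripted_fixture):
        _, _, _, _, result, _ = scripted_fixture
        f = result.features
        assert (f["Ln_um"] <= f["muscle_length_um"] * 1.05).all()

    def test_adding_a_polar_nucleus_never_decreases_ln(self):
        geom = vertical_geometry()
        cx = geom.medial_axis[0, 0]
        inner = [disk_blob(1, cx, 100), disk_blob(2, cx, 180)]
        ln0, _ = longitudinal_spread(straighten(frame_of(geom, *inner), geom), geom)
        outer = inner + [disk_blob(3, cx, 260)]
        ln1, _ = longitudinal_spread(straighten(frame_of(geom, *outer), geom), geom)
        assert ln1 >= ln0


class TestLateral:
    @staticmethod
    def row_extent_oracle(blobs):
        """Brute-force per-row extents: group the raw disk pixels by their
        y row and take the pixel-footprint extent (max - min + 1)."""
        rows = {}
        for b in blobs:
            for y, x in b.pixels:
                rows.setdefault(y, []).append(x)
        return np.mean([max(xs) - min(xs) + 1 for xs in rows.values()])

    def test_single_row_extent(self):
        """A single row of nuclei on the axis: every occupied band's width is
        the disk chord (+1 px footprint); M_lat is their mean."""
        geom = vertical_geometry(height=300, width=40)
        cx = geom.medial_axis[0, 0]
        blobs = [disk_blob(i + 1, cx, 40 + 60 * i, r=6) for i in range(4)]
        sf = straighten(frame_of(geom, *blobs), geom)
        mlat, nmlat = lateral_spread(sf, geom, u=300)
        expected = self.row_extent_oracle(blobs)
        assert mlat / 1.25 == pytest.approx(expected, rel=0.02)
        assert nmlat == pytest.approx(mlat / (40 * 1.25), rel=0.05)

    def test_two_rows_widen_lateral_spread(self):
        """Nuclei paired at +/-8 px about the axis at the same arc positions
        widen every occupied band by twice the offset."""
        geom = vertical_geometry(height=300, width=60)
        cx = geom.medial_axis[0, 0]
        single = [disk_blob(i + 1, cx, 40 + 60 * i, r=6) for i in range(4)]
        double = [
            disk_blob(2 * i + 1 + s, cx + (8 if s else -8), 40 + 60 * i, r=6)
            for i in range(4)
            for s in (0, 1)
        ]
        m1, _ = lateral_spread(straighten(frame_of(geom, *single), geom), geom, u=300)
        m2, _ = lateral_spread(straighten(frame_of(geom, *double), geom), geom, u=300)
        assert m2 == pytest.approx(m1 + 2 * 8 * 1.25, rel=0.02)
        assert m2 == pytest.approx(self.row_extent_oracle(double) * 1.25, rel=0.02)

    def test_boundary_hugging_nuclei_give_nmlat_near_one(self):
        geom = vertical_geometry(height=200, width=24)
        cx = geom.medial_axis[0, 0]
        blobs = [
            disk_blob(1, cx - 6, 100, r=6),
            disk_blob(2, cx + 6, 100, r=6),
        ]
        _, nmlat = lateral_spread(straighten(frame_of(geom, *blobs), geom), geom, u=200)
        assert nmlat == pytest.approx(1.0, abs=0.12)

    def test_empty_frame_flagged(self):
        geom = vertical_geometry()
        mlat, nmlat = lateral_spread(
            straighten(frame_of(geom), geom), geom, u=100
        )
        assert math.isnan(mlat) and math.isnan(nmlat)


class TestQualitativeOrderings:
    """The worked three-timepoint comparison: polar frames maximize NM_lon,
    laterally spread frames maximize M_lat, and NM_lat is invariant when
    nuclei and cell widths scale together."""

    def test_polar_frame_maximizes_nmlon(self):
        geom = vertical_geometry(height=300, width=40)
        cx = geom.medial_axis[0, 0]
        polar = [disk_blob(1, cx, 20), disk_blob(2, cx, 290)]
        clustered = [disk_blob(1, cx, 140), disk_blob(2, cx, 170)]
        nm = {}
        for name, blobs in (("polar", polar), ("clustered", clustered)):
            sf = straighten(frame_of(geom, *blobs), geom)
            nm[name] = longitudinal_spread(sf, geom)[1]
        assert nm["polar"] > nm["clustered"]

    def test_spread_frame_maximizes_mlat(self):
        geom = vertical_geometry(height=300, width=60)
        cx = geom.medial_axis[0, 0]
        rows = [disk_blob(1, cx - 10, 100), disk_blob(2, cx + 10, 100)]  # same band
        axis_row = [disk_blob(1, cx, 100), disk_blob(2, cx, 160)]
        m_rows = lateral_spread(straighten(frame_of(geom, *rows), geom), geom, u=300)[0]
        m_axis = lateral_spread(straighten(frame_of(geom, *axis_row), geom), geom, u=300)[0]
        assert m_rows > m_axis

    def test_nmlat_scale_invariance(self):
        """Scaling nuclear offsets with the cell width leaves NM_lat unchanged."""
        narrow = vertical_geometry(height=300, width=30)
        wide = vertical_geometry(height=300, width=60)
        out = {}
        for geom, off, r in ((narrow, 5, 5), (wide, 10, 10)):
            cx = geom.medial_axis[0, 0]
            blobs = [disk_blob(1, cx - off, 100, r=r), disk_blob(2, cx + off, 200, r=r)]
            out[geom.mask.shape] = lateral_spread(
                straighten(frame_of(geom, *blobs), geom), geom, u=300
            )[1]
        vals = list(out.values())
        assert vals[0] == pytest.approx(vals[1], rel=0.1)


class TestStraighteningConsistency:
    def test_straight_muscle_features_match_unstraightened(self):
        """For a straight muscle, straightening is a rigid transform: features
        computed from raw pixel coordinates agree within 2%."""
        geom = vertical_geometry(height=300, width=40)
        cx = geom.medial_axis[0, 0]
        blobs = [disk_blob(i + 1, cx + (-1) ** i * 6, 50 + 55 * i) for i in range(5)]
        sf = straighten(frame_of(geom, *blobs), geom)
        ln, _ = longitudinal_spread(sf, geom)
        raw = np.vstack([b.pixels for b in blobs]).astype(float)
        ln_raw = (raw[:, 0].max() - raw[:, 0].min()) * 1.25
        assert ln == pytest.approx(ln_raw, rel=0.02)
        hull_nsd = nsd(sf, geom)
        from scipy.spatial import ConvexHull

        raw_nsd = ConvexHull(raw[:, ::-1]).volume * 1.25**2 / geom.area_um2
        assert hull_nsd == pytest.approx(raw_nsd, rel=0.02)


def test_feature_record_time_alignment(scripted_fixture):
    cfg, movie, boundaries, gt, result, truth = scripted_fixture
    f = result.features
    assert len(f) == movie.n_frames
    # he_frame=0, 30-min frames: frame 48 is +24 h
    row = f[f["frame"] == 48].iloc[0]
    assert row["time_h_after_HE"] == pytest.approx(24.0)
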