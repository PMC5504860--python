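"""Straightening of nuclei along the muscle medial axis and the nuclear
spatial-pattern features.

Straightening expresses every nucleus in medial-axis coordinates: dy is
the arc length of the foot point m of its centroid on the axis, dx the
signed perpendicular offset (left of the axis negative, right positive),
and alpha the angle between the axis tangent at m and the image y axis.
The nucleus is translated so its centroid sits at (X +/- dx, dy) and
rotated about the centroid by -alpha, so that a straight vertical muscle
is a fixed point of the transform.  X is a constant offset keeping all
x coordinates nonnegative.

Features (straightened frame, physical units):

* NSD     = area of convex hull of all nuclear pixels / muscle area
* L_n     = extent of nuclear pixels along the axis; NM_lon = L_n / L_c
* M_lat   = mean width Wn_i of the nuclear structure across arc-length
  bands; NM_lat = mean of Wn_i / Wc_i over the same bands

Wn_i is the pixel-footprint extent (max - min + 1 px) of straightened
nuclear pixels in band i; empty bands are excluded by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io_formats import FEATURE_COLUMNS, Movie
from .muscle_geometry import MuscleGeometry
from .nuclear_segmentation import NucleusBlobSet

log = logging.getLogger(__name__)


@dataclass
class StraightenedNucleus:
    label: int
    dx: float                 # signed perpendicular offset (px)
    dy: float                 # arc length of the foot point (px)
    alpha: float              # tangent-vs-y-axis angle (rad)
    foot: tuple[float, float]  # m, on the medial axis (x, y) px
    points: np.ndarray        # straightened pixel centres, (N, 2) float (x, y)
    centroid: tuple[float, float]  # straightened centroid (x, y)


@dataclass
class StraightenedFrame:
    frame: int
    X: float
    nuclei: list[StraightenedNucleus] = field(default_factory=list)

    def all_points(self) -> np.ndarray:
        if not self.nuclei:
            return np.empty((0, 2))
        return np.vstack([n.points for n in self.nuclei])


@dataclass
class FeatureParams:
    u: int | None = None            # width samples; None -> ~1 per px of arc
    include_empty_bands: bool = False
    nsd_use_straightened_area: bool = False


def _foot_point(geom: MuscleGeometry, p: np.ndarray) -> tuple[int, float]:
    """Index of the nearest medial-axis vertex to p and its distance;
    equidistant vertices resolve to the one nearer the axis start."""
    d = np.linalg.norm(geom.medial_axis - p[None, :], axis=1)
    return int(d.argmin()), float(d.min())  # argmin: first minimum = nearer start


def straighten(blobs: NucleusBlobSet, geom: MuscleGeometry, X: float | None = None) -> StraightenedFrame:
    """Map every nucleus into straightened medial-axis coordinates."""
    if X is None:
        X = math.ceil(geom.width_profile_um.max() / geom.pixel_size_um) + 2.0
    tangents = geom.tangents()
    out = StraightenedFrame(blobs.frame, X)
    for blob in blobs.blobs:
        c = np.array(blob.centroid, dtype=float)
        j, dx = _foot_point(geom, c)
        m = geom.medial_axis[j]
        t = tangents[j]
        dy = float(geom.arc_length_px[j])
        offset = c - m
        # side of the axis: cross(offset, tangent) > 0 -> right (+)
        side = 1.0 if (offset[0] * t[1] - offset[1] * t[0]) >= 0 else -1.0
        alpha = math.atan2(t[0], t[1])  # angle from the +y axis
        # rotate pixel offsets about the centroid by -alpha
        ca, sa = math.cos(-alpha), math.sin(-alpha)
        rot = np.array([[ca, -sa], [sa, ca]])
        pix_xy = blob.pixels[:, ::-1].astype(float)  # (x, y)
        rel = pix_xy - c
        new_centroid = np.array([X + side * dx, dy])
        pts = rel @ rot.T + new_centroid
        out.nuclei.append(
            StraightenedNucleus(
                blob.label, side * dx, dy, alpha, (float(m[0]), float(m[1])),
                pts, (float(new_centroid[0]), float(new_centroid[1])),
            )
        )
    return out


def nsd(straightened: StraightenedFrame, geom: MuscleGeometry) -> float:
    """Nuclear spatial density: convex-hull area of all straightened nuclear
    pixels over the muscle area.  Degenerate point sets give 0."""
    pts = straightened.all_points()
    if len(pts) < 3:
        log.debug("frame %d: <3 nuclear pixels, NSD degenerate", straightened.frame)
        return 0.0
    try:
        hull_area_px2 = ConvexHull(pts).volume  # 2D: volume == area
    except QhullError:
        log.debug("frame %d: collinear nuclear pixels, NSD degenerate", straightened.frame)
        return 0.0
    return hull_area_px2 * geom.pixel_size_um**2 / geom.area_um2


def longitudinal_spread(straightened: StraightenedFrame, geom: MuscleGeometry) -> tuple[float, float]:
    """(L_n, NM_lon): extent of nuclear pixels along the medial axis (um)
    and its L_c-normalized form."""
    pts = straightened.all_points()
    if len(pts) == 0:
        return float("nan"), float("nan")
    ln_um = float(pts[:, 1].max() - pts[:, 1].min()) * geom.pixel_size_um
    return ln_um, ln_um / geom.length_um


def lateral_spread(
    straightened: StraightenedFrame,
    geom: MuscleGeometry,
    u: int | None = None,
    include_empty_bands: bool = False,
) -> tuple[float, float]:
    """(M_lat, NM_lat): mean nuclear width across arc-length bands (um) and
    its muscle-width-normalized form.

    The axis is split into u contiguous bands of height L_c/u anchored at
    the axis start; Wn_i is the pixel-footprint x-extent of straightened
    nuclear pixels in band i and Wc_i the muscle width at the band's
    sample point.
    """
    if u is None:
        u = len(geom.width_profile_um)
    pts = straightened.all_points()
    if len(pts) == 0:
        return float("nan"), float("nan")
    length_px = geom.length_px
    band = np.clip(
        (pts[:, 1] / length_px * u).astype(int), 0, u - 1
    )
    wn = np.zeros(u)
    occupied = np.zeros(u, dtype=bool)
    for i in range(u):
        sel = band == i
        if not sel.any():
            continue
        xs = pts[sel, 0]
        wn[i] = (xs.max() - xs.min() + 1.0) * geom.pixel_size_um
        occupied[i] = True
    wc = geom.width_profile_um
    if len(wc) != u:
        # resample the stored width profile onto the band sample points
        src = np.linspace(0, 1, len(wc))
        wc = np.interp(np.linspace(0, 1, u), src, geom.width_profile_um)
    use = np.ones(u, dtype=bool) if include_empty_bands else occupied
    if not use.any():
        return float("nan"), float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(wc > 0, wn / np.where(wc > 0, wc, 1.0), 0.0)
    return float(wn[use].mean()), float(ratio[use].mean())


def feature_record(
    blobs: NucleusBlobSet,
    geom: MuscleGeometry,
    params: FeatureParams | None = None,
) -> dict:
    """All spatial-pattern features of one frame."""
    params = params or FeatureParams()
    sf = straighten(blobs, geom)
    ln_um, nm_lon = longitudinal_spread(sf, geom)
    mlat, nmlat = lateral_spread(sf, geom, params.u, params.include_empty_bands)
    return {
        "frame": blobs.frame,
        "NSD": nsd(sf, geom),
        "Ln_um": ln_um,
        "NMlon": nm_lon,
        "Mlat_um": mlat,
        "NMlat": nmlat,
        "muscle_length_um": geom.length_um,
        "muscle_area_um2": geom.area_um2,
        "mean_width_um": geom.mean_width_um,
    }


def feature_series(
    movie: Movie,
    geoms: dict[int, MuscleGeometry],
    cleaned_blobs: list[NucleusBlobSet],
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Per-frame feature table; time is hours after head eversion when the
    movie carries an HE frame.  Frames without a boundary are skipped."""
    rows = []
    for bs in cleaned_blobs:
        if bs.frame not in geoms:
            log.warning("frame %d lacks a muscle boundary; skipped", bs.frame)
            continue
        rec = feature_record(bs, geoms[bs.frame], params)
        rec["time_h_after_HE"] = movie.time_h(bs.frame)
        rows.append(rec)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
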