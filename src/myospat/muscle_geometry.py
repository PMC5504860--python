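"""Muscle geometry: mask rasterization, medial axis, width profile, morphology.

The medial axis is the backbone of the whole feature set: nuclei are
expressed in (perpendicular offset, arc length) coordinates relative to it,
the muscle length L_c is its arc length, and the width profile W_c,i is
sampled perpendicular to it at equally spaced arc-length positions.

Construction (the source material leaves it open): skeletonize the mask,
take the longest geodesic path through the skeleton (which prunes side
branches), fit a smoothing spline, orient it so the end with smaller y
comes first, and optionally extend both ends along their tangents to the
mask boundary so the axis spans pole to pole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import interpolate
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    pass


@dataclass
class MuscleGeometry:
    """Rasterized muscle with medial-axis parametrization.

    ``medial_axis`` is an (N, 2) array of (x, y) points ordered from the
    start pole (smaller y) to the end pole; ``arc_length_px`` the matching
    cumulative arc length.  Lengths/areas are in physical units.
    """

    mask: np.ndarray
    medial_axis: np.ndarray
    arc_length_px: np.ndarray
    pixel_size_um: float
    width_profile_um: np.ndarray
    centroid: tuple[float, float]
    area_um2: float

    @property
    def length_px(self) -> float:
        return float(self.arc_length_px[-1])

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size_um

    @property
    def mean_width_um(self) -> float:
        return float(np.mean(self.width_profile_um))

    def tangents(self) -> np.ndarray:
        """Unit tangent at every medial-axis vertex (central differences)."""
        d = np.gradient(self.medial_axis, axis=0)
        norms = np.linalg.norm(d, axis=1)
        norms[norms == 0] = 1.0
        return d / norms[:, None]


def rasterize(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a boundary polygon: a pixel is inside iff its centre is.

    Polygons partly outside the image are clipped; a polygon entirely
    outside yields an all-false mask with a warning.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    # shoelace area; degenerate (zero-area) polygons are rejected
    x, y = polygon[:, 0], polygon[:, 1]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 == 0:
        raise GeometryError("polygon has zero area")
    mask = polygon2mask(shape, polygon[:, ::-1])  # polygon2mask wants (row, col)
    if not mask.any():
        log.warning("polygon rasterized to an empty mask (outside image?)")
    return mask


def morphology(mask: np.ndarray, pixel_size_um: float) -> tuple[tuple[float, float], float]:
    """Centroid (x, y) in px and area in um^2 of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    centroid = (float(xs.mean()), float(ys.mean()))
    area = float(ys.size) * pixel_size_um**2
    return centroid, area


def _skeleton_longest_path(mask: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the skeleton, as ordered (x, y) points."""
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if ys.size < 2:
        raise GeometryError("skeleton degenerate (mask too small?)")
    pts = set(zip(ys.tolist(), xs.tolist()))
    g = nx.Graph()
    for (py, px) in pts:
        g.add_node((py, px))
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                q = (py + dy, px + dx)
                if q in pts:
                    g.add_edge((py, px), q, weight=float(np.hypot(dy, dx)))
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) < 2:  # cycle or single pixel: fall back to all nodes
        endpoints = list(g.nodes)
    # double-sweep: farthest node from an arbitrary endpoint, then farthest
    # from that one, gives the diameter path on (near-)tree skeletons
    src = endpoints[0]
    dist = nx.single_source_dijkstra_path_length(g, src)
    far1 = max(dist, key=dist.get)
    dist1, paths1 = nx.single_source_dijkstra(g, far1)
    far2 = max(dist1, key=dist1.get)
    path = paths1[far2]
    return np.array([(px, py) for (py, px) in path], dtype=float)


def _smooth_path(path_xy: np.ndarray, smoothing_per_point: float = 2.0) -> np.ndarray:
    """Fit a smoothing spline to the skeleton path, resampled at ~0.5 px."""
    n = len(path_xy)
    if n < 8:
        return path_xy
    # parametrize by cumulative chord length
    seg = np.linalg.norm(np.diff(path_xy, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    total = u[-1]
    if total == 0:
        return path_xy
    k = min(3, n - 1)
    tck, _ = interpolate.splprep(
        [path_xy[:, 0], path_xy[:, 1]], u=u / total, s=smoothing_per_point * n, k=k
    )
    n_out = max(int(round(total * 2)), 8)
    uu = np.linspace(0, 1, n_out)
    xs, ys = interpolate.splev(uu, tck)
    return np.column_stack([xs, ys])


def _inside(mask: np.ndarray, x: float, y: float) -> bool:
    iy, ix = int(round(y)), int(round(x))
    return 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and bool(mask[iy, ix])


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Extend both path ends along their end tangents until leaving the mask."""
    out = [path]
    for which in (0, -1):
        if which == 0:
            tangent = path[0] - path[min(5, len(path) - 1)]
            origin = path[0]
        else:
            tangent = path[-1] - path[max(-6, -len(path))]
            origin = path[-1]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        ext = []
        p = origin.copy()
        while True:
            p = p + tangent * step
            if not _inside(mask, p[0], p[1]):
                break
            ext.append(p.copy())
        if ext:
            ext_arr = np.array(ext)
            out = [ext_arr[::-1], *out] if which == 0 else [*out, ext_arr]
    return np.vstack(out)


def medial_axis_polyline(
    mask: np.ndarray,
    extend_to_boundary: bool = True,
    min_elongation: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pruned, smoothed centerline of an elongated mask.

    Returns (points, arc_length): (N, 2) (x, y) points ordered so the end
    with smaller y comes first, and the cumulative arc length in px.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = cc_label(mask)
    n_comp = labels.max()
    if n_comp == 0:
        raise GeometryError("empty mask")
    if n_comp > 1:
        raise GeometryError(f"mask has {n_comp} connected components, expected 1")
    props = regionprops(labels)[0]
    minor = props.axis_minor_length or 1.0
    elongation = props.axis_major_length / minor
    if elongation < min_elongation:
        raise GeometryError(
            f"mask elongation {elongation:.2f} below {min_elongation}; not an elongated muscle"
        )
    path = _skeleton_longest_path(mask)
    path = _smooth_path(path)
    if extend_to_boundary:
        path = _extend_to_boundary(path, mask)
    # orient: start at the pole with smaller y (ties: smaller x)
    a, b = path[0], path[-1]
    if (a[1], a[0]) > (b[1], b[0]):
        path = path[::-1]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return path, arc


def width_profile(
    mask: np.ndarray,
    axis_points: np.ndarray,
    arc_length_px: np.ndarray,
    u: int,
    pixel_size_um: float,
    step: float = 0.25,
) -> np.ndarray:
    """Chord widths W_c,i (um) perpendicular to the axis at u equally spaced
    arc-length samples.  Sample points that have drifted outside the mask are
    snapped to the nearest inside pixel (logged)."""
    if u < 2:
        raise ValueError("u must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    targets = np.linspace(0, arc_length_px[-1], u)
    widths = np.empty(u)
    tangents = np.gradient(axis_points, axis=0)
    for i, s in enumerate(targets):
        j = int(np.searchsorted(arc_length_px, s, side="left"))
        j = min(max(j, 0), len(axis_points) - 1)
        p = axis_points[j].astype(float)
        t = tangents[j]
        tn = np.linalg.norm(t)
        t = t / tn if tn else np.array([0.0, 1.0])
        normal = np.array([-t[1], t[0]])
        if not _inside(mask, p[0], p[1]):
            ys, xs = np.nonzero(mask)
            k = np.argmin((xs - p[0]) ** 2 + (ys - p[1]) ** 2)
            log.debug("width sample %d outside mask; snapped", i)
            p = np.array([xs[k], ys[k]], dtype=float)
        w = 0.0
        for sign in (1.0, -1.0):
            q = p.copy()
            while _inside(mask, q[0], q[1]):
                q = q + sign * step * normal
            w += np.linalg.norm(q - p) - step  # last step left the mask
        widths[i] = max(w, 0.0) * pixel_size_um
    return widths


def default_u(length_px: float) -> int:
    """Default number of width samples: ~one per pixel of arc length."""
    return max(2, int(round(length_px)))


def save_overlay(
    geom: MuscleGeometry,
    path,
    image: np.ndarray | None = None,
    n_chords: int = 15,
) -> None:
    """Debug overlay PNG: boundary mask, medial axis and width chords."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if image is not None:
        ax.imshow(image, cmap="gray")
    ax.contour(geom.mask, levels=[0.5], colors="cyan", linewidths=0.8)
    ax.plot(geom.medial_axis[:, 0], geom.medial_axis[:, 1], "r-", lw=1)
    tangents = geom.tangents()
    idx = np.linspace(0, len(geom.medial_axis) - 1, n_chords).astype(int)
    for j in idx:
        p, t = geom.medial_axis[j], tangents[j]
        n = np.array([-t[1], t[0]])
        half = geom.width_profile_um[
            min(int(j / len(geom.medial_axis) * len(geom.width_profile_um)),
                len(geom.width_profile_um) - 1)
        ] / (2 * geom.pixel_size_um)
        ax.plot(
            [p[0] - half * n[0], p[0] + half * n[0]],
            [p[1] - half * n[1], p[1] + half * n[1]],
            "y-", lw=0.6,
        )
    ax.set_aspect("equal")
    ax.invert_yaxis()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def from_polygon(
    polygon: np.ndarray,
    shape: tuple[int, int],
    pixel_size_um: float,
    u: int | None = None,
    extend_to_boundary: bool = True,
) -> MuscleGeometry:
    """Full geometry pipeline: rasterize, medial axis, widths, morphology."""
    mask = rasterize(polygon, shape)
    axis, arc = medial_axis_polyline(mask, extend_to_boundary=extend_to_boundary)
    if u is None:
        u = default_u(arc[-1])
    widths = width_profile(mask, axis, arc, u, pixel_size_um)
    centroid, area = morphology(mask, pixel_size_um)
    return MuscleGeometry(mask, axis, arc, pixel_size_um, widths, centroid, area)
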