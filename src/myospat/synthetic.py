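"""Synthetic two-channel muscle movies with full ground truth.

The generator emulates the study conditions of pupal time-lapse imaging:
a capsule-shaped muscle cell (round-capped tube around a centerline) whose
width can change over time (atrophy/growth), internal nuclei that ride the
muscle and follow a scripted anti-polar -> polar migration program at
0-12 um/h, external (sarcolyte) nuclei that traverse the field
ballistically at 25-37 um/h, slow whole-muscle drift, bright cross-talk
artifacts near the muscle boundary in the nuclear channel, and additive
imaging noise.  Calibration defaults to 1.25 um/px and 30 min/frame.

Everything is deterministic given the seed, and every frame carries
ground truth: nucleus ids, classes, centroids, pixel sets and the muscle
boundary polygon, plus closed-form feature time courses for the scripted
program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .io_formats import BoundarySidecar, Movie
from .nuclear_tracking import Track

UM_PER_H_TO_PX_PER_FRAME = 0.5 / 1.25  # at default calibration


@dataclass
class SimConfig:
    image_size: tuple[int, int] = (512, 512)     # (H, W)
    n_frames: int = 50
    pixel_size_um: float = 1.25
    frame_interval_min: float = 30.0
    he_frame: int = 0
    # muscle geometry
    centerline: str = "straight"                 # straight | arc
    centerline_length_px: float = 400.0
    half_width_px: float = 20.0
    half_width_end_px: float | None = None       # width schedule (atrophy/growth)
    # nuclei
    n_internal: int = 10
    n_external: int = 3
    internal_speed_um_h: tuple[float, float] = (0.0, 12.0)
    external_speed_um_h: tuple[float, float] = (25.0, 37.0)
    nucleus_radius_px: float = 6.0
    min_spacing_px: float = 20.0
    # migration program: (start_frame, end_frame) windows and arc-fraction spreads
    anti_polar_window: tuple[int, int] | None = (4, 22)
    polar_window: tuple[int, int] | None = (28, 46)
    spread_initial: float = 0.80                 # fraction of centerline initially covered
    spread_min: float = 0.50                     # fraction at the end of anti-polar phase
    lateral_offset_px: float = 0.0               # two-row half-offset (0 = single row)
    # rendering / noise
    nucleus_amplitude: float = 180.0
    artifact_amplitude: float = 90.0
    artifacts_per_frame: int = 3
    noise_sigma: float = 6.0
    poisson_noise: bool = False
    drift_amplitude_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.internal_speed_um_h) < 0 or min(self.external_speed_um_h) < 0:
            raise ValueError("speeds must be nonnegative")
        for w in (self.anti_polar_window, self.polar_window):
            if w is not None and not (0 <= w[0] <= w[1] < self.n_frames):
                raise ValueError(f"migration window {w} outside movie duration")

    @property
    def px_per_frame_per_um_h(self) -> float:
        return (self.frame_interval_min / 60.0) / self.pixel_size_um


@dataclass
class GroundTruthFrame:
    ids: list[int]
    classes: list[str]
    centroids: np.ndarray                      # (N, 2) (x, y) px
    pixel_sets: list[np.ndarray]               # (n, 2) integer (y, x) per nucleus


@dataclass
class GroundTruth:
    frames: list[GroundTruthFrame]
    classes: dict[int, str]
    muscle_centroids: list[tuple[float, float]]
    config: SimConfig = field(repr=False, default=None)

    def internal_centroids(self, t: int) -> np.ndarray:
        gtf = self.frames[t]
        sel = [i for i, c in enumerate(gtf.classes) if c == "internal"]
        return gtf.centroids[sel] if sel else np.empty((0, 2))


# ---------------------------------------------------------------------------
# Centerline and migration program
# ---------------------------------------------------------------------------

def _centerline_points(cfg: SimConfig, drift: np.ndarray) -> np.ndarray:
    """Dense (x, y) polyline of the muscle centerline (before width caps)."""
    h, w = cfg.image_size
    n = max(int(cfg.centerline_length_px * 2), 32)
    s = np.linspace(0, 1, n)
    if cfg.centerline == "straight":
        x = np.full(n, w / 2.0)
        y0 = (h - cfg.centerline_length_px) / 2.0
        y = y0 + s * cfg.centerline_length_px
    elif cfg.centerline == "arc":
        # circular arc subtending 90 degrees with the requested arc length
        radius = cfg.centerline_length_px / (math.pi / 2)
        cx, cy = w / 2.0 - radius / 2.0, h / 2.0 - radius / 2.0
        theta = s * (math.pi / 2)
        x = cx + radius * np.sin(theta)
        y = cy + radius * (1 - np.cos(theta))
    else:
        raise ValueError(f"unknown centerline kind {cfg.centerline!r}")
    return np.column_stack([x, y]) + drift[None, :]


def _half_width(cfg: SimConfig, t: int) -> float:
    if cfg.half_width_end_px is None or cfg.n_frames <= 1:
        return cfg.half_width_px
    f = t / (cfg.n_frames - 1)
    return cfg.half_width_px + f * (cfg.half_width_end_px - cfg.half_width_px)


def _spread(cfg: SimConfig, t: int) -> float:
    """Scripted fraction of the centerline covered by internal nuclei."""
    s = cfg.spread_initial
    if cfg.anti_polar_window is not None:
        a0, a1 = cfg.anti_polar_window
        if t >= a1:
            s = cfg.spread_min
        elif t > a0:
            f = (t - a0) / (a1 - a0)
            s = cfg.spread_initial + f * (cfg.spread_min - cfg.spread_initial)
    if cfg.polar_window is not None:
        p0, p1 = cfg.polar_window
        if t >= p1:
            s = cfg.spread_initial
        elif t > p0:
            f = (t - p0) / (p1 - p0)
            s = cfg.spread_min + f * (cfg.spread_initial - cfg.spread_min)
    return s


def internal_arc_positions(cfg: SimConfig, t: int) -> np.ndarray:
    """Scripted arc-length positions (px along the centerline) of the
    internal nuclei at frame t: evenly spaced across the current spread,
    centred on the midpoint."""
    spread = _spread(cfg, t) * cfg.centerline_length_px
    mid = cfg.centerline_length_px / 2.0
    if cfg.n_internal == 1:
        return np.array([mid])
    return mid + np.linspace(-0.5, 0.5, cfg.n_internal) * spread


def _check_program_speed(cfg: SimConfig) -> None:
    max_step = cfg.internal_speed_um_h[1] * cfg.px_per_frame_per_um_h
    for t in range(cfg.n_frames - 1):
        step = np.abs(internal_arc_positions(cfg, t + 1) - internal_arc_positions(cfg, t))
        if step.max() > max_step + 1e-9:
            raise ValueError(
                f"migration program moves a nucleus {step.max():.2f} px between frames "
                f"{t} and {t + 1}, exceeding the internal speed cap {max_step:.2f} px"
            )


def _check_spacing(cfg: SimConfig) -> None:
    for t in (0, cfg.n_frames - 1, *(w for win in (cfg.anti_polar_window,) if win for w in win)):
        pos = internal_arc_positions(cfg, min(t, cfg.n_frames - 1))
        if cfg.n_internal > 1 and np.diff(np.sort(pos)).min() < cfg.min_spacing_px:
            raise ValueError(
                "internal nuclei cannot satisfy the minimum spacing "
                f"({cfg.min_spacing_px} px) at frame {t}; use fewer nuclei or a "
                "longer muscle"
            )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _point_on_polyline(poly: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc length s along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0, arc[-1]))
    j = int(np.searchsorted(arc, s, side="right")) - 1
    j = min(max(j, 0), len(poly) - 2)
    f = (s - arc[j]) / max(arc[j + 1] - arc[j], 1e-12)
    p = poly[j] + f * (poly[j + 1] - poly[j])
    t = poly[j + 1] - poly[j]
    return p, t / max(np.linalg.norm(t), 1e-12)


def _disk_pixels(cx: float, cy: float, r: float, shape: tuple[int, int]) -> np.ndarray:
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r))
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r))
    ys, xs = np.mgrid[max(y0, 0):min(y1 + 1, shape[0]), max(x0, 0):min(x1 + 1, shape[1])]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    return np.column_stack([ys[inside], xs[inside]])


def simulate(cfg: SimConfig) -> tuple[Movie, BoundarySidecar, GroundTruth]:
    """Render the scripted scene into a two-channel movie with ground truth."""
    _check_program_speed(cfg)
    _check_spacing(cfg)
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    r = cfg.nucleus_radius_px
    sigma_b = r / math.sqrt(2 * math.log(2))   # Gaussian blob with half-max radius r

    # whole-muscle drift: slow smooth excursion, <= ~1 px/frame
    phases = rng.uniform(0, 2 * math.pi, size=2)
    tt = np.arange(cfg.n_frames)
    drift = np.column_stack(
        [
            cfg.drift_amplitude_px * np.sin(2 * math.pi * tt / max(cfg.n_frames, 1) + phases[0]),
            cfg.drift_amplitude_px * np.sin(2 * math.pi * tt / max(cfg.n_frames, 1) + phases[1]),
        ]
    )

    # internal jitter: per-nucleus biased random walk on top of the program,
    # clamped so program + jitter stays within the internal speed range
    max_step = cfg.internal_speed_um_h[1] * cfg.px_per_frame_per_um_h
    jitter_scale = 0.4

    # external nuclei: ballistic crossings, staggered entry
    ext_speed = rng.uniform(*cfg.external_speed_um_h, size=cfg.n_external)
    ext_speed_px = ext_speed * cfg.px_per_frame_per_um_h
    ext_theta = rng.uniform(0, 2 * math.pi, size=cfg.n_external)
    ext_start = np.column_stack(
        [rng.uniform(0.2 * w, 0.8 * w, cfg.n_external),
         rng.uniform(0.2 * h, 0.8 * h, cfg.n_external)]
    )
    ext_t0 = rng.integers(0, max(cfg.n_frames // 2, 1), size=cfg.n_external)

    frames = np.zeros((cfg.n_frames, 2, h, w), dtype=np.uint8)
    polygons: dict[int, np.ndarray] = {}
    gt_frames: list[GroundTruthFrame] = []
    muscle_centroids: list[tuple[float, float]] = []
    classes = {i: "internal" for i in range(cfg.n_internal)}
    classes.update({cfg.n_internal + j: "external" for j in range(cfg.n_external)})

    jitter = np.zeros((cfg.n_internal, 2))
    for t in range(cfg.n_frames):
        centerline = _centerline_points(cfg, drift[t])
        hw = _half_width(cfg, t)
        capsule = LineString(centerline).buffer(hw, cap_style="round")
        poly = np.asarray(capsule.exterior.coords)
        polygons[t] = poly

        # muscle mask & centroid (analytic rasterization via shapely bounds)
        from skimage.draw import polygon2mask

        mask = polygon2mask((h, w), poly[:, ::-1])
        ys, xs = np.nonzero(mask)
        muscle_centroids.append((float(xs.mean()), float(ys.mean())))

        # --- internal nuclei
        arc_pos = internal_arc_positions(cfg, t)
        step = rng.uniform(-1, 1, size=(cfg.n_internal, 2)) * jitter_scale
        jitter = np.clip(jitter + step, -1.5, 1.5)
        ids, cls, cents, pixel_sets = [], [], [], []
        for i in range(cfg.n_internal):
            p, tang = _point_on_polyline(centerline, arc_pos[i])
            normal = np.array([-tang[1], tang[0]])
            side = 1.0 if i % 2 == 0 else -1.0
            c = p + normal * side * cfg.lateral_offset_px + jitter[i]
            ids.append(i)
            cls.append("internal")
            cents.append(c)
            pixel_sets.append(_disk_pixels(c[0], c[1], r, (h, w)))
        # --- external nuclei
        for j in range(cfg.n_external):
            tj = t - ext_t0[j]
            c = ext_start[j] + tj * ext_speed_px[j] * np.array(
                [math.cos(ext_theta[j]), math.sin(ext_theta[j])]
            )
            if not (-r <= c[0] < w + r and -r <= c[1] < h + r):
                continue
            ids.append(cfg.n_internal + j)
            cls.append("external")
            cents.append(c)
            pixel_sets.append(_disk_pixels(c[0], c[1], r, (h, w)))
        cents_arr = np.array(cents) if cents else np.empty((0, 2))
        gt_frames.append(GroundTruthFrame(ids, cls, cents_arr, pixel_sets))

        # --- rendering
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        cyto = np.full((h, w), 12.0)
        cyto[mask] = 110.0
        rim = mask ^ ndimage.binary_erosion(mask, iterations=3)
        cyto[rim] = 170.0
        cyto = ndimage.gaussian_filter(cyto, 1.0)

        nuc = np.full((h, w), 10.0)
        for c in cents:
            d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2
            nuc += cfg.nucleus_amplitude * np.exp(-d2 / (2 * sigma_b**2))
        # cross-talk artifacts: moderate-contrast blobs hugging the outside of
        # the muscle boundary (debris attached to the sarcolemma)
        n_art = cfg.artifacts_per_frame
        if n_art > 0 and cfg.artifact_amplitude > 0:
            art_s = rng.uniform(0, capsule.exterior.length, size=n_art)
            cline = LineString(centerline)
            for s in art_s:
                pt = capsule.exterior.interpolate(float(s))
                q = cline.interpolate(cline.project(pt))
                n_vec = np.array([pt.x - q.x, pt.y - q.y])
                n_vec /= max(np.linalg.norm(n_vec), 1e-9)
                cx_, cy_ = pt.x + 4.0 * n_vec[0], pt.y + 4.0 * n_vec[1]
                d2 = (xx - cx_) ** 2 + (yy - cy_) ** 2
                nuc += cfg.artifact_amplitude * np.exp(-d2 / (2 * (0.8 * sigma_b) ** 2))
        if cfg.poisson_noise:
            nuc = rng.poisson(np.clip(nuc, 0, None)).astype(np.float64)
            cyto = rng.poisson(np.clip(cyto, 0, None)).astype(np.float64)
        if cfg.noise_sigma > 0:
            nuc = nuc + rng.normal(0, cfg.noise_sigma, size=(h, w))
            cyto = cyto + rng.normal(0, cfg.noise_sigma, size=(h, w))
        frames[t, 0] = np.clip(cyto, 0, 255).astype(np.uint8)
        frames[t, 1] = np.clip(nuc, 0, 255).astype(np.uint8)

    movie = Movie(frames, cfg.pixel_size_um, cfg.frame_interval_min, cfg.he_frame)
    return movie, BoundarySidecar(polygons), GroundTruth(gt_frames, classes, muscle_centroids, cfg)


# ---------------------------------------------------------------------------
# Closed-form feature truth for the scripted program
# ---------------------------------------------------------------------------

def scripted_feature_truth(cfg: SimConfig, u: int | None = None) -> pd.DataFrame:
    """Expected feature time courses computed from the scripted geometry
    alone (no imaging, no jitter): straight-muscle closed forms.

    L_n is the pixel extent of the ideal nuclear disks along the axis;
    L_c the pole-to-pole capsule length; M_lat averages the disk chord
    extents over occupied unit arc-length bands.
    """
    if cfg.centerline != "straight":
        raise ValueError("closed-form truth is defined for the straight centerline")
    r = cfg.nucleus_radius_px
    rows = []
    for t in range(cfg.n_frames):
        hw = _half_width(cfg, t)
        lc_px = cfg.centerline_length_px + 2 * hw
        pos = internal_arc_positions(cfg, t) + hw  # arc measured from the pole
        ln_px = (pos.max() + r) - (pos.min() - r)
        # occupied unit bands and their chord extents
        n_bands = max(int(round(lc_px)), 1) if u is None else u
        band_h = lc_px / n_bands
        centres = (np.arange(n_bands) + 0.5) * band_h
        wn = np.zeros(n_bands)
        for p in pos:
            d = np.abs(centres - p)
            sel = d < r
            chord = 2 * np.sqrt(np.clip(r * r - d[sel] ** 2, 0, None)) + 1.0
            if cfg.lateral_offset_px > 0:
                chord = chord + 2 * cfg.lateral_offset_px  # two rows: union extent
            wn[sel] = np.maximum(wn[sel], chord)
        occ = wn > 0
        mlat_px = wn[occ].mean() if occ.any() else float("nan")
        wc_um = 2 * hw * cfg.pixel_size_um
        rows.append(
            {
                "frame": t,
                "Ln_um": ln_px * cfg.pixel_size_um,
                "Lc_um": lc_px * cfg.pixel_size_um,
                "NMlon": ln_px / lc_px,
                "Mlat_um": mlat_px * cfg.pixel_size_um,
                "NMlat": (mlat_px * cfg.pixel_size_um) / wc_um,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motion-level track fixture for classifier evaluation
# ---------------------------------------------------------------------------

def _disk_overlap_fraction(d: float, r: float) -> float:
    """Intersection of two radius-r disks at distance d over the disk area."""
    if d >= 2 * r:
        return 0.0
    inter = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r * r - d * d)
    return inter / (math.pi * r * r)


def simulate_track_set(
    n_internal: int = 20,
    n_external: int = 20,
    n_transitions: int = 10,
    internal_speed_um_h: tuple[float, float] = (0.0, 12.0),
    external_speed_um_h: tuple[float, float] = (25.0, 37.0),
    pixel_size_um: float = 1.25,
    frame_interval_min: float = 30.0,
    nucleus_radius_px: float = 6.0,
    seed: int = 0,
) -> tuple[list[Track], dict[int, str]]:
    """Tracks whose per-transition displacements are drawn from the internal
    and external speed ranges, with overlaps from the disk-overlap closed
    form.  Returns (tracks, true class per track id)."""
    rng = np.random.default_rng(seed)
    px_per_um_h = (frame_interval_min / 60.0) / pixel_size_um
    tracks: list[Track] = []
    truth: dict[int, str] = {}
    tid = 1
    for cls, n, speed in (
        ("internal", n_internal, internal_speed_um_h),
        ("external", n_external, external_speed_um_h),
    ):
        for _ in range(n):
            v = rng.uniform(*speed, size=n_transitions)
            d = v * px_per_um_h
            o = [_disk_overlap_fraction(di, nucleus_radius_px) for di in d]
            tr = Track(tid, 0, n_transitions, D=list(map(float, d)), O=o)
            tracks.append(tr)
            truth[tid] = cls
            tid += 1
    return tracks, truth
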