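"""Nuclear tracking by motion-compensated mutual nearest-neighbour matching.

Blobs in consecutive frames are matched by centroid proximity after
compensating whole-muscle motion (translation by the muscle-centroid
displacement).  Three relationships arise between adjacent time points:

* Case I   - mutual nearest neighbours: the same nuclear region; its track
  continues.
* Case II  - a frame-t+1 blob whose nearest neighbour at t does not
  reciprocate: a nucleus that broke off a clump; it starts a new track.
* Case III - a frame-t blob whose nearest neighbour at t+1 does not
  reciprocate: it joined a clump; its track terminates at t.

Tracks are therefore maximal chains of mutually-nearest blobs; no gap
closing is attempted across missed detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .nuclear_segmentation import NucleusBlobSet


class Case(Enum):
    I = "mutual"
    II = "new_track"
    III = "terminates"


@dataclass
class Track:
    id: int
    t_s: int
    t_e: int
    labels: dict[int, int] = field(default_factory=dict)   # frame -> blob label
    D: list[float] = field(default_factory=list)           # per-transition displacement (px)
    O: list[float] = field(default_factory=list)           # per-transition overlap fraction

    @property
    def n_transitions(self) -> int:
        return self.t_e - self.t_s

    def __post_init__(self) -> None:
        if self.t_e < self.t_s:
            raise ValueError("t_e must be >= t_s")


@dataclass
class TrackTable:
    tracks: list[Track]
    grid: dict[int, dict[int, int]]        # frame -> {label -> track id}
    alignment: dict[int, tuple[float, float]]  # frame t -> (dx, dy) applied to t

    def track(self, tid: int) -> Track:
        return next(t for t in self.tracks if t.id == tid)

    def to_grid_table(self) -> dict[int, dict[int, int]]:
        """frame -> {track id -> label}, the T-by-X representation."""
        out: dict[int, dict[int, int]] = {}
        for frame, row in self.grid.items():
            out[frame] = {tid: lab for lab, tid in row.items()}
        return out


def compensate_motion(
    centroids_t: np.ndarray,
    muscle_centroid_t: tuple[float, float] | None,
    muscle_centroid_t1: tuple[float, float] | None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Shift frame-t blob centroids by the muscle-centroid displacement
    (c_{t+1} - c_t) so static nuclei align across frames.  Returns the
    shifted centroids and the (dx, dy) shift; missing centroids give a
    zero shift."""
    if muscle_centroid_t is None or muscle_centroid_t1 is None:
        return np.asarray(centroids_t, dtype=float), (0.0, 0.0)
    dx = muscle_centroid_t1[0] - muscle_centroid_t[0]
    dy = muscle_centroid_t1[1] - muscle_centroid_t[1]
    shifted = np.asarray(centroids_t, dtype=float) + np.array([dx, dy])
    return shifted, (dx, dy)


def _nearest(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Index of the nearest dst point for every src point; distance ties are
    broken by the smaller index (= smaller blob label)."""
    d = np.linalg.norm(src[:, None, :] - dst[None, :, :], axis=2)
    return d.argmin(axis=1)  # argmin returns the first (smallest-index) minimum


def match_frames(
    centroids_t_aligned: np.ndarray,
    centroids_t1: np.ndarray,
) -> list[tuple[Case, int | None, int | None]]:
    """Mutual-NN matching between aligned frame-t and frame-t+1 centroids.

    Returns (case, index_t, index_t1) triples with 0-based blob indices;
    Case II has index_t None, Case III has index_t1 None.
    """
    n_t, n_t1 = len(centroids_t_aligned), len(centroids_t1)
    events: list[tuple[Case, int | None, int | None]] = []
    if n_t == 0:
        return [(Case.II, None, j) for j in range(n_t1)]
    if n_t1 == 0:
        return [(Case.III, i, None) for i in range(n_t)]
    fwd = _nearest(centroids_t_aligned, centroids_t1)   # t -> t+1
    bwd = _nearest(centroids_t1, centroids_t_aligned)   # t+1 -> t
    matched_t1 = set()
    for i in range(n_t):
        j = fwd[i]
        if bwd[j] == i:
            events.append((Case.I, i, int(j)))
            matched_t1.add(int(j))
        else:
            events.append((Case.III, i, None))
    for j in range(n_t1):
        if j not in matched_t1:
            events.append((Case.II, None, j))
    return events


def _overlap_fraction(pix_t: np.ndarray, pix_t1: np.ndarray, shift: tuple[float, float]) -> float:
    """|aligned pixels(t) intersect pixels(t+1)| / min(areas); alignment shift
    rounded to whole pixels for the integer pixel sets."""
    sx, sy = int(round(shift[0])), int(round(shift[1]))
    a = {(y + sy, x + sx) for y, x in map(tuple, pix_t)}
    b = set(map(tuple, pix_t1))
    inter = len(a & b)
    denom = min(len(a), len(b))
    return inter / denom if denom else 0.0


def build_tracks(
    blob_sets: list[NucleusBlobSet],
    muscle_centroids: list[tuple[float, float] | None] | None = None,
) -> TrackTable:
    """Track blobs across the whole movie.

    Every blob of frame 0 starts a track; tracks extend on Case I,
    terminate on Case III and start on Case II.  Per transition the
    motion-compensated centroid displacement D_i and the overlap fraction
    O_i are recorded.
    """
    n_frames = len(blob_sets)
    if muscle_centroids is None:
        muscle_centroids = [None] * n_frames
    tracks: list[Track] = []
    grid: dict[int, dict[int, int]] = {t: {} for t in range(n_frames)}
    alignment: dict[int, tuple[float, float]] = {}
    next_id = 1
    # open tracks: blob index in current frame -> Track
    open_tracks: dict[int, Track] = {}
    if n_frames == 0:
        return TrackTable([], {}, {})
    for i, blob in enumerate(blob_sets[0].blobs):
        tr = Track(next_id, 0, 0, labels={0: blob.label})
        tracks.append(tr)
        grid[0][blob.label] = tr.id
        open_tracks[i] = tr
        next_id += 1
    for t in range(n_frames - 1):
        bs_t, bs_t1 = blob_sets[t], blob_sets[t + 1]
        cents_t = bs_t.centroids()
        shifted, shift = compensate_motion(
            cents_t, muscle_centroids[t], muscle_centroids[t + 1]
        )
        alignment[t] = shift
        events = match_frames(shifted, bs_t1.centroids())
        new_open: dict[int, Track] = {}
        for case, i, j in events:
            if case is Case.I:
                tr = open_tracks[i]
                blob_t, blob_t1 = bs_t.blobs[i], bs_t1.blobs[j]
                d = float(np.linalg.norm(shifted[i] - np.array(blob_t1.centroid)))
                o = _overlap_fraction(blob_t.pixels, blob_t1.pixels, shift)
                tr.t_e = t + 1
                tr.labels[t + 1] = blob_t1.label
                tr.D.append(d)
                tr.O.append(o)
                grid[t + 1][blob_t1.label] = tr.id
                new_open[j] = tr
            elif case is Case.II:
                blob_t1 = bs_t1.blobs[j]
                tr = Track(next_id, t + 1, t + 1, labels={t + 1: blob_t1.label})
                tracks.append(tr)
                grid[t + 1][blob_t1.label] = tr.id
                new_open[j] = tr
                next_id += 1
            # Case III: track simply stays closed
        open_tracks = new_open
    return TrackTable(tracks, grid, alignment)
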