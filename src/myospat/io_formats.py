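"""Readers and writers for every on-disk artefact of the pipeline.

Movies are multi-page TIFFs with the two colour channels interleaved per
time point (page 2t = cytoplasm, page 2t+1 = nuclei).  Muscle boundaries,
track tables, feature tables and ground truth travel as JSON/CSV sidecars.
All pixel coordinates are 0-based with x increasing to the right and y
increasing downwards, and refer to pixel centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

COORDINATE_CONVENTION = "0-based, x right, y down, pixel centres"

#: physical calibration of the reference acquisitions (um per pixel, minutes
#: per frame); carried in sidecars/config rather than parsed from TIFF tags.
DEFAULT_PIXEL_SIZE_UM = 1.25
DEFAULT_FRAME_INTERVAL_MIN = 30.0


class MovieFormatError(ValueError):
    """Raised when a TIFF cannot be interpreted as a two-channel movie."""


@dataclass
class Movie:
    """A two-channel 2D time series with physical calibration.

    ``frames`` has shape (T, 2, H, W); channel 0 is the muscle cytoplasm
    marker, channel 1 the nuclear marker.  ``he_frame`` is the frame index
    of head eversion, the temporal reference for cross-sample alignment.
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    he_frame: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise MovieFormatError(
                f"expected frames of shape (T, 2, H, W), got {self.frames.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    def channel(self, frame: int, channel: int) -> np.ndarray:
        return self.frames[frame, channel]

    def time_h(self, frame: int) -> float:
        """Hours relative to head eversion (or to frame 0 if HE is unset)."""
        ref = self.he_frame if self.he_frame is not None else 0
        return (frame - ref) * self.frame_interval_min / 60.0


def read_movie(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    he_frame: int | None = None,
    n_channels: int = 2,
) -> Movie:
    """Read an interleaved multi-page TIFF movie, preserving intensities bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise MovieFormatError(f"expected a stack of 2D pages, got shape {pages.shape}")
    if pages.shape[0] % n_channels != 0:
        raise MovieFormatError(
            f"{pages.shape[0]} pages are not divisible by {n_channels} channels"
        )
    t = pages.shape[0] // n_channels
    frames = pages.reshape(t, n_channels, pages.shape[1], pages.shape[2])
    return Movie(frames, pixel_size_um, frame_interval_min, he_frame)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as an interleaved multi-page TIFF (channels fastest)."""
    t, c, h, w = movie.frames.shape
    tifffile.imwrite(Path(path), movie.frames.reshape(t * c, h, w))


def max_intensity_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a z-stack (z, y, x) to a 2D image."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty 3D array (z, y, x)")
    return stack.max(axis=0)


# ---------------------------------------------------------------------------
# Muscle boundary sidecars
# ---------------------------------------------------------------------------

@dataclass
class BoundarySidecar:
    """Per-frame closed muscle boundary polygons in pixel coordinates."""

    polygons: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for frame, poly in self.polygons.items():
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(
                    f"frame {frame}: polygon must be an (N>=3, 2) vertex list"
                )
            clean[int(frame)] = poly
        self.polygons = clean

    def frames(self) -> list[int]:
        return sorted(self.polygons)

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.polygons[frame]

    def __contains__(self, frame: int) -> bool:
        return frame in self.polygons

    def validate_against(self, n_frames: int) -> None:
        bad = [f for f in self.polygons if f < 0 or f >= n_frames]
        if bad:
            raise ValueError(f"boundary frames {bad} outside movie range 0..{n_frames - 1}")


def read_boundaries(path: str | Path) -> BoundarySidecar:
    with open(path) as fh:
        payload = json.load(fh)
    frames = payload["frames"] if isinstance(payload, dict) and "frames" in payload else payload
    return BoundarySidecar({int(k): np.asarray(v, dtype=float) for k, v in frames.items()})


def write_boundaries(sidecar: BoundarySidecar, path: str | Path) -> None:
    payload = {
        "coordinate_convention": COORDINATE_CONVENTION,
        "frames": {str(f): sidecar[f].tolist() for f in sidecar.frames()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Track and feature tables
# ---------------------------------------------------------------------------

def tracks_to_table(grid: dict[int, dict[int, int]], n_frames: int) -> pd.DataFrame:
    """Build the T-by-X track table (rows = frames, columns = track ids,
    cells = per-frame blob labels; missing cells are nulls)."""
    track_ids = sorted({tid for row in grid.values() for tid in row})
    table = pd.DataFrame(
        index=pd.RangeIndex(n_frames, name="frame"),
        columns=track_ids,
        dtype="Int64",
    )
    for frame, row in grid.items():
        for tid, label in row.items():
            table.loc[frame, tid] = label
    return table


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="frame")


def read_tracks(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="frame")
    table.columns = [int(c) for c in table.columns]
    return table.astype("Int64")


FEATURE_COLUMNS = [
    "frame",
    "time_h_after_HE",
    "NSD",
    "Ln_um",
    "NMlon",
    "Mlat_um",
    "NMlat",
    "muscle_length_um",
    "muscle_area_um2",
    "mean_width_um",
]


def write_features(series: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    series.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
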