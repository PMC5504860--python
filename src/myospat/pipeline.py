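"""Pipeline orchestration: segment -> track -> classify -> purge ->
straighten/features, driven by one structured config.

Every stage is a pure function of its inputs and parameters; the runner
writes each stage's artefacts (CSV/JSON) next to the outputs together
with the resolved config, so stages can be re-run and audited.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, muscle_geometry, spatial_features
from .io_formats import BoundarySidecar, Movie
from .nuclear_segmentation import NucleusBlobSet, SegmentationParams, segment_frame
from .nuclear_tracking import TrackTable, build_tracks
from .spatial_features import FeatureParams
from .track_classification import (
    ClassifierParams,
    classify_tracks,
    purge_external,
    track_summary,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    movie_path: str = ""
    boundaries_path: str = ""
    out_dir: str = "out"
    pixel_size_um: float = io_formats.DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = io_formats.DEFAULT_FRAME_INTERVAL_MIN
    he_frame: int | None = None
    extend_axis_to_boundary: bool = True
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    features: FeatureParams = field(default_factory=FeatureParams)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        nested = {
            "segmentation": SegmentationParams,
            "classifier": ClassifierParams,
            "features": FeatureParams,
        }
        kwargs = {}
        for key, sub_cls in nested.items():
            sub = payload.pop(key, {})
            unknown = set(sub) - {f.name for f in dataclasses.fields(sub_cls)}
            if unknown:
                raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
            kwargs[key] = sub_cls(**sub)
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)} - set(nested)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    movie: Movie
    geoms: dict[int, muscle_geometry.MuscleGeometry]
    blob_sets: list[NucleusBlobSet]
    table: TrackTable
    classes: dict[int, str]
    cleaned: list[NucleusBlobSet]
    features: pd.DataFrame
    summary: list[dict]


def _stage(name: str, frame: int | None = None):
    where = f"stage '{name}'" + (f", frame {frame}" if frame is not None else "")
    return where


def run_pipeline(
    movie: Movie,
    boundaries: BoundarySidecar,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run segment -> track -> classify -> purge -> features on a movie."""
    config = config or PipelineConfig()
    boundaries.validate_against(movie.n_frames)

    geoms: dict[int, muscle_geometry.MuscleGeometry] = {}
    for t in boundaries.frames():
        try:
            geoms[t] = muscle_geometry.from_polygon(
                boundaries[t], movie.shape, movie.pixel_size_um,
                u=config.features.u,
                extend_to_boundary=config.extend_axis_to_boundary,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with stage context
            raise RuntimeError(f"{_stage('geometry', t)}: {exc}") from exc
    log.info("geometry: %d frames", len(geoms))

    blob_sets = []
    for t in range(movie.n_frames):
        if t not in geoms:
            blob_sets.append(NucleusBlobSet(t, np.zeros(movie.shape, dtype=np.int32), []))
            continue
        try:
            blob_sets.append(
                segment_frame(movie.channel(t, 1), geoms[t].mask, config.segmentation, frame=t)
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"{_stage('segmentation', t)}: {exc}") from exc
    log.info("segmentation: %s blobs/frame", [len(b) for b in blob_sets[:5]])

    centroids = [geoms[t].centroid if t in geoms else None for t in range(movie.n_frames)]
    table = build_tracks(blob_sets, centroids)
    classes = classify_tracks(table, config.classifier)
    cleaned = purge_external(blob_sets, table, classes)
    feats = spatial_features.feature_series(movie, geoms, cleaned, config.features)
    summary = track_summary(table, classes, movie.pixel_size_um, movie.frame_interval_min)
    return PipelineResult(movie, geoms, blob_sets, table, classes, cleaned, feats, summary)


def write_artefacts(result: PipelineResult, out_dir: str | Path, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    # blob table
    rows = [
        {"frame": bs.frame, "label": b.label, "cx": b.centroid[0], "cy": b.centroid[1],
         "area_px": b.area_px}
        for bs in result.blob_sets for b in bs.blobs
    ]
    pd.DataFrame(rows, columns=["frame", "label", "cx", "cy", "area_px"]).to_csv(
        out / "blobs.csv", index=False
    )
    # tracks: T-by-X table
    grid = result.table.to_grid_table()
    io_formats.write_tracks(
        io_formats.tracks_to_table(
            {f: {t: l for t, l in row.items()} for f, row in grid.items()},
            result.movie.n_frames,
        ),
        out / "tracks.csv",
    )
    # per-transition table
    trans = [
        {"track": tr.id, "frame": tr.t_s + i + 1, "D_px": d, "O_frac": o}
        for tr in result.table.tracks for i, (d, o) in enumerate(zip(tr.D, tr.O))
    ]
    pd.DataFrame(trans, columns=["track", "frame", "D_px", "O_frac"]).to_csv(
        out / "transitions.csv", index=False
    )
    pd.DataFrame(result.summary).to_csv(out / "track_summary.csv", index=False)
    io_formats.write_features(result.features, out / "features.csv")
    geo = [
        {"frame": t, "Lc_um": g.length_um, "area_um2": g.area_um2,
         "centroid_x": g.centroid[0], "centroid_y": g.centroid[1]}
        for t, g in sorted(result.geoms.items())
    ]
    pd.DataFrame(geo).to_csv(out / "geometry.csv", index=False)


def sweep_lambda(
    table_or_tracks,
    truth_classes: dict[int, str],
    lambdas: np.ndarray,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Classification performance (accuracy, FPR, FNR) at a range of
    lambda thresholds, against ground-truth track classes."""
    from .stats_compare import evaluate_classification
    from .track_classification import track_cost

    tracks = table_or_tracks.tracks if isinstance(table_or_tracks, TrackTable) else table_or_tracks
    params = params or ClassifierParams()
    costs = {tr.id: track_cost(tr, params.n_is_timepoints) for tr in tracks}
    ids = [tr.id for tr in tracks if tr.id in truth_classes]
    truth = [truth_classes[i] for i in ids]
    rows = []
    for lam in lambdas:
        pred = [
            "external" if (np.isfinite(costs[i]) and costs[i] > lam) else "internal"
            for i in ids
        ]
        ev = evaluate_classification(pred, truth)
        rows.append(
            {"lambda": float(lam), "accuracy": ev.accuracy,
             "fpr": ev.false_positive_rate, "fnr": ev.false_negative_rate}
        )
    return pd.DataFrame(rows)
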