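"""Shared fixtures: synthetic movies at two scales plus pipeline runs.

The session-scoped 50-frame fixtures are expensive (~0.5 min together) and
are shared by the end-to-end and acceptance tests; module tests use the
small 256x256 scenes.
"""

from __future__ import annotations

import numpy as np
import pytest

from myospat.pipeline import PipelineConfig, run_pipeline
from myospat.synthetic import SimConfig, simulate, scripted_feature_truth


def small_config(**overrides) -> SimConfig:
    """A fast 256x256 scene: 3 internal nuclei, no migration program."""
    defaults = dict(
        image_size=(256, 256),
        n_frames=6,
        centerline_length_px=180.0,
        half_width_px=16.0,
        n_internal=3,
        n_external=0,
        anti_polar_window=None,
        polar_window=None,
        min_spacing_px=20.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def scripted_fixture():
    """Default 50-frame anti-polar -> polar scene without external nuclei,
    with its pipeline result and closed-form feature truth."""
    cfg = SimConfig(n_frames=50, seed=7, n_external=0)
    movie, boundaries, gt = simulate(cfg)
    result = run_pipeline(movie, boundaries, PipelineConfig())
    truth = scripted_feature_truth(cfg)
    return cfg, movie, boundaries, gt, result, truth


@pytest.fixture(scope="session")
def mixed_fixture():
    """50-frame scene with external (sarcolyte) nuclei crossing the muscle."""
    cfg = SimConfig(n_frames=50, seed=7)
    movie, boundaries, gt = simulate(cfg)
    result = run_pipeline(movie, boundaries, PipelineConfig())
    return cfg, movie, boundaries, gt, result


@pytest.fixture(scope="session")
def small_fixture():
    cfg = small_config()
    movie, boundaries, gt = simulate(cfg)
    return cfg, movie, boundaries, gt


def track_truth_classes(result, gt, max_dist: float = 10.0) -> dict[int, str]:
    """Ground-truth class per track id by majority vote over the track's
    blobs (nearest ground-truth nucleus per frame)."""
    votes: dict[int, list[str]] = {}
    for t, row in result.table.grid.items():
        gtf = gt.frames[t]
        if len(gtf.centroids) == 0:
            continue
        for blob in result.blob_sets[t].blobs:
            tid = row.get(blob.label)
            if tid is None:
                continue
            d = np.linalg.norm(gtf.centroids - np.array(blob.centroid), axis=1)
            j = int(d.argmin())
            if d[j] <= max_dist:
                votes.setdefault(tid, []).append(gtf.classes[j])
    return {
        tid: max(set(v), key=v.count) for tid, v in votes.items() if v
    }


def instance_accuracy(result, gt, max_dist: float = 10.0) -> float:
    """Per-blob-appearance classification accuracy against ground truth."""
    correct = total = 0
    for t, row in result.table.grid.items():
        gtf = gt.frames[t]
        if len(gtf.centroids) == 0:
            continue
        for blob in result.blob_sets[t].blobs:
            d = np.linalg.norm(gtf.centroids - np.array(blob.centroid), axis=1)
            j = int(d.argmin())
            if d[j] > max_dist:
                continue
            pred = result.classes.get(row.get(blob.label), "internal")
            total += 1
            correct += pred == gtf.classes[j]
    return correct / total if total else float("nan")
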