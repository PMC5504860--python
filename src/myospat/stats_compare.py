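"""Group comparison of feature series and evaluation against ground truth.

Genotype groups are compared per time point with a two-sided Mann-Whitney
U test; a time point is called significant when -log10(p) exceeds 1.3
(p = 0.05, strict).  Migration-phase deltas summarize the change of the
longitudinal nuclear spread L_n over the anti-polar and polar migration
windows.  Detection and classification are scored against ground truth
with the usual count-based rates:

    FNR = FN / (FN + TP)        FPR = FP / (FP + TP)
    Accuracy = (TP + TN) / (TP + FP + TN + FN)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

SIGNIFICANCE_NEGLOG10 = 1.3  # -log10(0.05), strict
EXACT_MAX_COMBINED_N = 16


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    @property
    def false_negative_rate(self) -> float:
        denom = self.FN + self.TP
        return self.FN / denom if denom else 0.0

    @property
    def false_positive_rate(self) -> float:
        denom = self.FP + self.TP
        return self.FP / denom if denom else 0.0

    @property
    def accuracy(self) -> float:
        denom = self.TP + self.FP + self.TN + self.FN
        return (self.TP + self.TN) / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney U per time point
# ---------------------------------------------------------------------------

def mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for combined n <= 16 without ties,
    normal approximation with tie correction otherwise.  Returns (U, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_COMBINED_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def align_replicates(
    series: list[pd.DataFrame],
    feature: str,
    grid_step_h: float = 0.5,
) -> pd.DataFrame:
    """Snap replicate feature series onto a common time grid.

    Each replicate DataFrame needs `time_h_after_HE` and the feature
    column.  Values are assigned to the nearest grid point within half a
    step (15 min for the default 30-min grid).  Returns a grid x replicate
    table (NaN where a replicate has no sample)."""
    cols = {}
    for i, df in enumerate(series):
        t = df["time_h_after_HE"].to_numpy(dtype=float)
        v = df[feature].to_numpy(dtype=float)
        snapped = np.round(t / grid_step_h) * grid_step_h
        ok = np.abs(t - snapped) <= grid_step_h / 2 + 1e-9
        cols[i] = pd.Series(v[ok], index=snapped[ok]).groupby(level=0).mean()
    out = pd.DataFrame(cols)
    out.index.name = "time_h"
    return out.sort_index()


def mannwhitney_series(
    group_a: list[pd.DataFrame],
    group_b: list[pd.DataFrame],
    feature: str,
    grid_step_h: float = 0.5,
) -> pd.DataFrame:
    """Per-timepoint Mann-Whitney U between two replicate groups.

    Time points with fewer than 2 values in either group are skipped.
    Returns columns time_h, feature, U, p, neglog10p, significant.
    """
    ta = align_replicates(group_a, feature, grid_step_h)
    tb = align_replicates(group_b, feature, grid_step_h)
    rows = []
    n_skipped = 0
    for t in sorted(set(ta.index) & set(tb.index)):
        a = ta.loc[t].dropna().to_numpy()
        b = tb.loc[t].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            n_skipped += 1
            continue
        u, p = mannwhitney(a, b)
        neglog = -np.log10(p) if p > 0 else np.inf
        rows.append(
            {
                "time_h": t,
                "feature": feature,
                "U": u,
                "p": p,
                "neglog10p": neglog,
                "significant": bool(neglog > SIGNIFICANCE_NEGLOG10),
            }
        )
    if n_skipped:
        log.info("skipped %d time points with <2 replicates", n_skipped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Migration-phase deltas
# ---------------------------------------------------------------------------

def detect_phase_windows(
    series: pd.DataFrame,
    feature: str = "Ln_um",
    smooth_window: int = 5,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Auto-detect (anti-polar, polar) windows from a moving-median-smoothed
    feature series: anti-polar runs from the global maximum to the global
    minimum, polar from that minimum to the subsequent maximum.

    Plateaus are handled by taking the boundary nearest the transition:
    the last max before the decline, the first/last frame of the minimum
    plateau, and the first max after the rise (2% of the series range
    counts as 'equal')."""
    t = series["time_h_after_HE"].to_numpy(dtype=float)
    v = (
        pd.Series(series[feature].to_numpy(dtype=float))
        .rolling(smooth_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    tol = 0.02 * (v.max() - v.min())
    at_min = np.nonzero(v <= v.min() + tol)[0]
    i_min_first, i_min_last = int(at_min[0]), int(at_min[-1])
    head = v[: i_min_first + 1]
    at_max1 = np.nonzero(head >= head.max() - tol)[0]
    i_start = int(at_max1[-1])
    tail = v[i_min_last:]
    at_max2 = np.nonzero(tail >= tail.max() - tol)[0]
    i_end = i_min_last + int(at_max2[0])
    return (t[i_start], t[i_min_first]), (t[i_min_last], t[i_end])


def migration_deltas(
    group: list[pd.DataFrame],
    windows: dict[str, tuple[float, float]] | None = None,
    feature: str = "Ln_um",
) -> pd.DataFrame:
    """Per-phase change of a feature (end - start) per replicate, with the
    group mean and a 95% t-interval.

    ``windows`` maps phase name to (start_h, end_h); when omitted the
    anti-polar and polar windows are auto-detected per replicate.
    """
    rows = []
    for phase_idx, phase in enumerate(("anti_polar", "polar")):
        deltas = []
        for df in group:
            if windows is not None and phase in windows:
                w = windows[phase]
            else:
                w = detect_phase_windows(df, feature)[phase_idx]
            t = df["time_h_after_HE"].to_numpy(dtype=float)
            if w[0] < t.min() - 1e-9 or w[1] > t.max() + 1e-9:
                raise ValueError(f"window {w} outside series range [{t.min()}, {t.max()}]")
            v = df[feature].to_numpy(dtype=float)
            v0 = v[int(np.argmin(np.abs(t - w[0])))]
            v1 = v[int(np.argmin(np.abs(t - w[1])))]
            deltas.append(v1 - v0)
        deltas = np.asarray(deltas, dtype=float)
        mean = float(deltas.mean())
        if len(deltas) > 1 and deltas.std(ddof=1) > 0:
            lo, hi = sps.t.interval(0.95, len(deltas) - 1, loc=mean, scale=sps.sem(deltas))
        else:
            lo = hi = mean
        rows.append(
            {"phase": phase, "n": len(deltas), "mean_delta": mean,
             "ci95_lo": float(lo), "ci95_hi": float(hi)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection / classification evaluation
# ---------------------------------------------------------------------------

def evaluate_detection(
    predicted: np.ndarray,
    truth: np.ndarray,
    match_radius_px: float = 5.0,
) -> EvalCounts:
    """Greedy one-to-one matching of predicted to true centroids by
    ascending distance within the match radius."""
    predicted = np.asarray(predicted, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(predicted) == 0 or len(truth) == 0:
        return EvalCounts(TP=0, FP=len(predicted), FN=len(truth))
    d = cdist(predicted, truth)
    pairs = [
        (d[i, j], i, j)
        for i in range(len(predicted))
        for j in range(len(truth))
        if d[i, j] <= match_radius_px
    ]
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    return EvalCounts(TP=tp, FP=len(predicted) - tp, FN=len(truth) - tp)


def evaluate_classification(predicted: list[str], truth: list[str]) -> EvalCounts:
    """Score internal/external track classes; positive class = internal
    (an external nucleus called internal is a false positive)."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    c = EvalCounts()
    for p, t in zip(predicted, truth):
        if t == "internal":
            if p == "internal":
                c.TP += 1
            else:
                c.FN += 1
        else:
            if p == "internal":
                c.FP += 1
            else:
                c.TN += 1
    return c
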