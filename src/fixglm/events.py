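"""Eye-movement event detection and fixation analysis.

The detector follows standard velocity/acceleration parser semantics: a
saccade opens where smoothed gaze speed and acceleration both exceed their
thresholds and the displacement across the candidate interval exceeds a
minimum motion; everything between saccades is a fixation summarised by its
centroid. Default thresholds: 30 deg/s velocity, 8000 deg/s^2 acceleration,
0.1 deg minimum displacement (the published "0.1 deg/s" motion minimum is a
units typo; displacement is the standard parser meaning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, EventStream, GazeRecording, ROILayout

#: Regions entering rank statistics by default (forehead/chin are assigned
#: but rarely fixated, so they are excluded from percentage tables).
DEFAULT_STAT_ROIS = ("brows", "eyes", "corrugator", "nose", "mouth", "out")


@dataclass(frozen=True)
class DetectorThresholds:
    velocity_deg_s: float = 30.0
    acceleration_deg_s2: float = 8000.0
    motion_deg: float = 0.1
    smooth_samples: int = 5
    min_fixation_ms: float = 40.0

    def __post_init__(self) -> None:
        if min(self.velocity_deg_s, self.acceleration_deg_s2, self.motion_deg) <= 0:
            raise ValueError("detector thresholds must be > 0")


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def detect_eye_events(
    gaze: GazeRecording,
    thresholds: DetectorThresholds | None = None,
    trial_id: int = 0,
) -> EventStream:
    """Segment a gaze trace into alternating fixations and saccades."""
    thr = thresholds if thresholds is not None else DetectorThresholds()
    if len(gaze) < 3:
        raise ValueError("need at least 3 samples to estimate velocity/acceleration")
    dt_s = 1.0 / gaze.rate
    vx = np.gradient(gaze.x_deg, dt_s)
    vy = np.gradient(gaze.y_deg, dt_s)
    speed = _smooth(np.hypot(vx, vy), thr.smooth_samples)
    accel = _smooth(np.abs(np.gradient(speed, dt_s)), thr.smooth_samples)

    fast = speed > thr.velocity_deg_s
    runs = _runs(fast)
    # merge candidate runs separated by less than the minimum fixation duration
    min_gap = int(round(thr.min_fixation_ms * gaze.rate / 1000.0))
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    saccades: list[tuple[int, int]] = []
    for start, stop in merged:
        disp = math.hypot(gaze.x_deg[stop - 1] - gaze.x_deg[start],
                          gaze.y_deg[stop - 1] - gaze.y_deg[start])
        if accel[start:stop].max(initial=0.0) >= thr.acceleration_deg_s2 \
                and disp >= thr.motion_deg:
            saccades.append((start, stop))

    rows: list[tuple] = []
    dt_ms = 1000.0 / gaze.rate
    t0 = gaze.time_ms[0]
    # fixations are the complementary spans
    bounds = [0] + [i for s in saccades for i in s] + [len(gaze)]
    rank = 0
    for k in range(0, len(bounds), 2):
        fs, fe = bounds[k], bounds[k + 1]
        if fe - fs < max(min_gap, 1):
            continue
        rank += 1
        rows.append((trial_id, "fixation", t0 + fs * dt_ms, (fe - fs) * dt_ms,
                     rank, "", np.nan, np.nan,
                     float(np.mean(gaze.x_deg[fs:fe])),
                     float(np.mean(gaze.y_deg[fs:fe]))))
    for start, stop in saccades:
        dx = gaze.x_deg[stop - 1] - gaze.x_deg[start]
        dy = gaze.y_deg[stop - 1] - gaze.y_deg[start]
        rows.append((trial_id, "saccade", t0 + start * dt_ms,
                     (stop - start) * dt_ms, np.nan, "",
                     math.hypot(dx, dy), math.degrees(math.atan2(-dy, dx)),
                     float(gaze.x_deg[start]), float(gaze.y_deg[start])))
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventStream(frame)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[::2], idx[1::2]))


# ---------------------------------------------------------------------------
# ROI assignment and rank-wise statistics
# ---------------------------------------------------------------------------

def assign_rois(events: EventStream, layout: ROILayout) -> EventStream:
    """Label each fixation with the ROI at its centroid position."""
    frame = events.frame.copy()
    is_fix = frame["event_type"] == "fixation"
    if frame.loc[is_fix, ["x_deg", "y_deg"]].isna().any().any():
        raise ValueError("fixation positions required for ROI assignment")
    frame.loc[is_fix, "roi"] = [
        layout.label_at_deg(x, y)
        for x, y in frame.loc[is_fix, ["x_deg", "y_deg"]].itertuples(index=False)
    ]
    return EventStream(frame)


def participant_roi_percentages(
    fixations: pd.DataFrame,
    ranks: Sequence[int] = (1, 2),
    rois: Sequence[str] = DEFAULT_STAT_ROIS,
    by: Sequence[str] = ("participant", "condition"),
) -> pd.DataFrame:
    """Per-participant ROI percentages for the requested fixation ranks.

    Percentages are computed within each (participant, condition, rank) cell
    over the listed ROIs only and sum to 100 in every cell.
    """
    df = fixations[fixations["rank"].isin(ranks) & fixations["roi"].isin(rois)]
    out = []
    for keys, grp in df.groupby([*by, "rank"]):
        counts = grp["roi"].value_counts()
        total = counts.sum()
        for roi in rois:
            out.append((*keys, roi, 100.0 * counts.get(roi, 0) / total))
    return pd.DataFrame(out, columns=[*by, "rank", "roi", "pct"])


def roi_rank_stats(
    fixations: pd.DataFrame,
    ranks: Sequence[int] = (1, 2),
    rois: Sequence[str] = DEFAULT_STAT_ROIS,
    by: Sequence[str] = ("participant", "condition"),
) -> pd.DataFrame:
    """Group-level ROI percentage table (mean of participant means + SEM).

    ``fixations`` needs columns rank, roi and the grouping columns in ``by``
    (the first of which must identify the participant). Cells with no
    fixation of the requested rank are flagged missing and excluded from the
    group mean.
    """
    per = participant_roi_percentages(fixations, ranks, rois, by)
    group_keys = [c for c in by if c != by[0]] + ["rank", "roi"]
    agg = per.groupby(group_keys)["pct"].agg(
        mean_pct="mean",
        sem_pct=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="size",
    ).reset_index()
    return agg


# ---------------------------------------------------------------------------
# Post hoc re-categorization by participant ratings
# ---------------------------------------------------------------------------

def recategorize_trials(
    ratings: pd.DataFrame,
    trials: pd.DataFrame,
    drop: Sequence[str] = ("fear",),
) -> pd.DataFrame:
    """Relabel each target trial with the participant's own category response.

    ``ratings``: columns participant, stimulus_id, response (and optionally
    arousal). ``trials``: columns participant, trial_id, stimulus_id. Trials
    whose response falls in ``drop`` (the badly recognised categories) are
    removed. Raises if any target trial lacks a rating row, listing the
    offending stimulus_ids.
    """
    merged = trials.merge(ratings[["participant", "stimulus_id", "response"]],
                          on=["participant", "stimulus_id"], how="left")
    missing = merged[merged["response"].isna()]
    if len(missing):
        ids = sorted(missing["stimulus_id"].unique().tolist())
        raise ValueError(f"missing ratings for stimuli: {ids}")
    merged = merged[~merged["response"].isin(drop)].copy()
    merged = merged.rename(columns={"response": "condition"})
    return merged.reset_index(drop=True)
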