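"""Shared in-memory containers for co-registered EEG / eye-tracking data.

Conventions
-----------
* All timestamps are milliseconds. Event onsets are *recording-relative*
  (time 0 = start of the continuous recording); lag axes of kernels and
  epochs are relative to their locking event.
* EEG amplitudes are microvolts, gaze positions degrees of visual angle.
* Tabular payloads are pandas DataFrames so they can be written/read as
  delimited text without bespoke parsers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Emotion categories used for target stimuli, plus the distractor class.
CATEGORIES = ("neutral", "happiness", "surprise", "fear", "disgust", "distractor")

#: Facial regions of interest; ``out`` is the background label.
ROI_NAMES = ("forehead", "brows", "corrugator", "eyes", "nose", "mouth", "chin", "out")

#: Columns of the delimited-text event schema.
EVENT_COLUMNS = (
    "trial_id", "event_type", "onset_ms", "duration_ms",
    "rank", "roi", "amplitude_deg", "orientation_deg", "x_deg", "y_deg",
)


@dataclass(frozen=True)
class Waveform:
    """A sampled waveform on an explicit lag axis (ms, uniform step)."""

    lags_ms: np.ndarray
    data: np.ndarray  # same length as lags_ms (1-D) or (lags, channels)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_ms, dtype=float)
        data = np.asarray(self.data, dtype=float)
        if lags.ndim != 1 or data.shape[0] != lags.shape[0]:
            raise ValueError("data must have one row per lag sample")
        steps = np.diff(lags)
        if lags.size > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("lag axis must be uniformly sampled")
        object.__setattr__(self, "lags_ms", lags)
        object.__setattr__(self, "data", data)

    @property
    def step_ms(self) -> float:
        return float(self.lags_ms[1] - self.lags_ms[0]) if self.lags_ms.size > 1 else np.nan

    @property
    def rate(self) -> float:
        return 1000.0 / self.step_ms

    def __add__(self, other: "Waveform") -> "Waveform":
        if not np.array_equal(self.lags_ms, other.lags_ms):
            raise ValueError("lag axes differ")
        return Waveform(self.lags_ms, self.data + other.data)

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.lags_ms, self.data * factor)


@dataclass(frozen=True)
class Modulation:
    """Additive amplitude offset for one (condition, site, latency window).

    ``target`` selects the kernel the offset is applied to ('s' by default,
    matching stimulus-locked condition effects; fixation-kernel modulations
    are used for EFRP-effect recovery experiments).
    """

    condition: str
    site: str
    window_ms: tuple[float, float]
    offset_uv: float
    target: str = "s"


@dataclass(frozen=True)
class KernelSet:
    """Latent event-locked waveforms used to synthesise EEG.

    s        -- potential evoked at image onset
    fp1      -- potential evoked at the first fixation after image onset
    fp2plus  -- potential evoked at rank-2+ fixations
    sp       -- saccadic potential
    """

    s: Waveform
    fp1: Waveform
    fp2plus: Waveform
    sp: Waveform
    modulations: tuple[Modulation, ...] = ()

    def __post_init__(self) -> None:
        rates = {round(w.rate, 6) for w in (self.s, self.fp1, self.fp2plus, self.sp)}
        if len(rates) != 1:
            raise ValueError("all kernels must share one sampling rate")

    @property
    def rate(self) -> float:
        return self.s.rate

    def kernel(self, klass: str) -> Waveform:
        return {"s": self.s, "fp1": self.fp1, "fp2plus": self.fp2plus, "sp": self.sp}[klass]

    def map_kernels(self, fn) -> "KernelSet":
        return KernelSet(fn(self.s), fn(self.fp1), fn(self.fp2plus), fn(self.sp),
                         self.modulations)


@dataclass(frozen=True)
class NoiseModel:
    """1/f^alpha Gaussian background-activity model."""

    spectrum_exponent: float = 1.0
    amplitude_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be >= 0")


@dataclass(frozen=True)
class StimulusCatalog:
    """Stimulus inventory: id, emotion category, target flag."""

    entries: pd.DataFrame  # columns: stimulus_id, category, is_target

    def __post_init__(self) -> None:
        df = self.entries
        if df["stimulus_id"].duplicated().any():
            raise ValueError("stimulus_ids must be unique")
        bad = ~df["category"].isin(CATEGORIES)
        if bad.any():
            raise ValueError(f"unknown categories: {sorted(df.loc[bad, 'category'].unique())}")
        if not (df["is_target"] == (df["category"] != "distractor")).all():
            raise ValueError("is_target must be true iff category != distractor")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_targets(self) -> int:
        return int(self.entries["is_target"].sum())

    def counts(self) -> dict[str, int]:
        return self.entries["category"].value_counts().to_dict()


@dataclass(frozen=True)
class TrialSchedule:
    """Trial timeline: fixation cross -> stimulus (2 s) -> grey inter-trial gap."""

    trials: pd.DataFrame
    # columns: trial_id, stimulus_id, cross_duration_ms, stimulus_duration_ms,
    #          inter_trial_gap_ms, stimulus_onset_ms (recording-relative), condition

    def __post_init__(self) -> None:
        if (self.trials["stimulus_duration_ms"] < 0).any():
            raise ValueError("stimulus_duration_ms must be >= 0")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def total_duration_ms(self) -> float:
        t = self.trials.iloc[-1]
        return float(t["stimulus_onset_ms"] + t["stimulus_duration_ms"] + t["inter_trial_gap_ms"])


class EventStream:
    """Typed, time-stamped stimulus/fixation/saccade events.

    Wraps a DataFrame with the :data:`EVENT_COLUMNS` schema. Fixations carry
    rank (1 = first fixation after image onset), ROI label, duration and
    position; saccades carry amplitude and orientation. Onsets are
    recording-relative milliseconds.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event frame missing columns {missing}")
        frame = frame.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        self.frame = frame.sort_values(["trial_id", "onset_ms"], kind="stable").reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        fix = self.fixations()
        for trial, grp in fix.groupby("trial_id"):
            onsets = grp["onset_ms"].to_numpy()
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(f"trial {trial}: fixation onsets not strictly increasing")
            ranks = grp["rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
                raise ValueError(f"trial {trial}: fixation ranks not consecutive from 1")

    def fixations(self) -> pd.DataFrame:
        return self.frame[self.frame["event_type"] == "fixation"]

    def saccades(self) -> pd.DataFrame:
        return self.frame[self.frame["event_type"] == "saccade"]

    def stimuli(self) -> pd.DataFrame:
        return self.frame[self.frame["event_type"] == "stimulus"]

    def for_trial(self, trial_id) -> "EventStream":
        return EventStream(self.frame[self.frame["trial_id"] == trial_id])

    def n_fixations(self) -> pd.Series:
        """Fixation count per trial (the L(i) of the superposition model)."""
        counts = self.fixations().groupby("trial_id").size()
        trials = self.stimuli()["trial_id"]
        return counts.reindex(trials, fill_value=0)

    def write_text(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="nan")

    @classmethod
    def read_text(cls, path: str | Path) -> "EventStream":
        frame = pd.read_csv(path, sep="\t")
        frame["roi"] = frame["roi"].fillna("").astype(str)
        frame["event_type"] = frame["event_type"].astype(str)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class GazeRecording:
    """Uniformly sampled gaze trace (degrees of visual angle)."""

    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.rate, atol=1e-6):
                raise ValueError("time axis inconsistent with stated rate")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "x_deg", np.asarray(self.x_deg, dtype=float))
        object.__setattr__(self, "y_deg", np.asarray(self.y_deg, dtype=float))

    def __len__(self) -> int:
        return self.time_ms.size

    def write_text(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.time_ms, "x_deg": self.x_deg,
                      "y_deg": self.y_deg}).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_text(cls, path: str | Path, rate: float | None = None) -> "GazeRecording":
        df = pd.read_csv(path, sep="\t")
        t = df["time_ms"].to_numpy(float)
        if rate is None:
            rate = 1000.0 / float(np.median(np.diff(t)))
        return cls(t, df["x_deg"].to_numpy(float), df["y_deg"].to_numpy(float), rate)


@dataclass(frozen=True)
class ContinuousEEG:
    """Continuous multichannel EEG, microvolts, [time x channels]."""

    data: np.ndarray
    rate: float
    ch_names: tuple[str, ...]
    reference: str = "acquisition"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        names = tuple(self.ch_names)
        if data.ndim != 2 or data.shape[1] != len(names):
            raise ValueError("data must be [time x channels] matching ch_names")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(data)):
            raise ValueError("EEG samples must be finite")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "ch_names", names)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.rate * 1000.0


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked EEG segments x_i(t), [epoch x time x channels]."""

    data: np.ndarray
    times_ms: np.ndarray  # lag axis relative to stimulus onset
    rate: float
    ch_names: tuple[str, ...]
    metadata: pd.DataFrame  # per-epoch: trial_id, condition, n_fixations, participant
    baseline_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times_ms, dtype=float)
        if data.ndim != 3:
            raise ValueError("epochs must be [epoch x time x channels]")
        if data.shape[1] != times.size or data.shape[2] != len(self.ch_names):
            raise ValueError("epoch array shape inconsistent with axes")
        if len(self.metadata) != data.shape[0]:
            raise ValueError("metadata must have one row per epoch")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times_ms", times)
        object.__setattr__(self, "ch_names", tuple(self.ch_names))
        object.__setattr__(self, "metadata", self.metadata.reset_index(drop=True))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times_ms, self.rate, self.ch_names,
                        self.metadata.loc[mask].reset_index(drop=True), self.baseline_ms)


@dataclass(frozen=True)
class ROILayout:
    """Facial-region label raster plus legend and pixel<->degree transform.

    ``labels`` is an integer raster (rows x cols, origin top-left); legend maps
    integer label -> ROI name; 0 is always the background ('out').
    ``deg_per_px`` and ``origin_deg`` place pixel (0, 0): the gaze position in
    degrees of pixel (row, col) is ``origin + (col, row) * deg_per_px``.
    """

    labels: np.ndarray
    legend: Mapping[int, str]
    deg_per_px: float
    origin_deg: tuple[float, float]  # (x, y) of pixel (0, 0) centre

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        legend = dict(self.legend)
        if labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if legend.get(0) != "out":
            raise ValueError("label 0 must be the background 'out'")
        present = set(np.unique(labels).tolist())
        if not present <= set(legend):
            raise ValueError("raster contains labels missing from the legend")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "legend", legend)

    def label_at_deg(self, x_deg: float, y_deg: float) -> str:
        col = int(round((x_deg - self.origin_deg[0]) / self.deg_per_px))
        row = int(round((y_deg - self.origin_deg[1]) / self.deg_per_px))
        if 0 <= row < self.labels.shape[0] and 0 <= col < self.labels.shape[1]:
            return self.legend[int(self.labels[row, col])]
        return "out"
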