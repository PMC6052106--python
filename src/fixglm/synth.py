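"""Synthetic co-registered EEG / eye-tracking generator.

Emulates the structure of a free-viewing emotional-face experiment: each
trial shows a fixation cross for a jittered 700-1200 ms, then a static face
for 2 s, followed by a grey inter-trial screen. During the stimulus the
simulated observer produces a fixation/saccade scanpath over facial regions
of interest; the EEG is the superposition of a stimulus-locked kernel s(t),
a first-fixation kernel fp1(t), a rank-2+ fixation kernel fp2plus(t) and a
saccadic kernel sp(t), shifted to the event timestamps, plus 1/f-type noise:

    x_i(t) = s(t) + fp1(t - tau_i^(1)) + sum_l fp2plus(t - tau_i^(l))
             + sum_l' sp(t - tau'_i^(l')) + n_i(t)

Default scanpath parameters are calibrated to the behavioral statistics of
the emulated study: ~4.74 fixations per 2-s trial, ~300 ms mean fixation
duration, first-fixation latency ~250 ms and second ~500 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CATEGORIES,
    EVENT_COLUMNS,
    ContinuousEEG,
    EventStream,
    GazeRecording,
    KernelSet,
    Modulation,
    NoiseModel,
    ROILayout,
    StimulusCatalog,
    TrialSchedule,
    Waveform,
)

#: Stimulus-set composition of the emulated database (70 targets + 48 distractors).
DEFAULT_COMPOSITION: dict[str, int] = {
    "neutral": 24, "happiness": 12, "surprise": 12,
    "fear": 10, "disgust": 12, "distractor": 48,
}


# ---------------------------------------------------------------------------
# Stimulus catalog and trial schedule
# ---------------------------------------------------------------------------

def make_stimulus_catalog(
    composition: Mapping[str, int] | None = None, seed: int = 0
) -> StimulusCatalog:
    """Build a shuffled stimulus inventory with the requested per-category counts."""
    composition = dict(DEFAULT_COMPOSITION if composition is None else composition)
    for cat, n in composition.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        if n < 0:
            raise ValueError(f"negative count for {cat!r}")
    rows = []
    for cat in CATEGORIES:
        for k in range(composition.get(cat, 0)):
            rows.append((f"{cat}_{k:03d}", cat, cat != "distractor"))
    df = pd.DataFrame(rows, columns=["stimulus_id", "category", "is_target"])
    rng = np.random.default_rng([seed, 101])
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return StimulusCatalog(df)


def make_trial_schedule(
    catalog: StimulusCatalog,
    seed: int = 0,
    cross_bounds_ms: tuple[float, float] = (700.0, 1200.0),
    stimulus_duration_ms: float = 2000.0,
    inter_trial_gap_ms: float = 4000.0,
) -> TrialSchedule:
    """Lay out trials on a continuous timeline with jittered fixation crosses."""
    if stimulus_duration_ms <= 0:
        raise ValueError("stimulus_duration_ms must be > 0")
    rng = np.random.default_rng([seed, 202])
    n = len(catalog)
    cross = rng.uniform(cross_bounds_ms[0], cross_bounds_ms[1], size=n)
    onset = 0.0
    rows = []
    for i in range(n):
        entry = catalog.entries.iloc[i]
        stim_onset = onset + cross[i]
        rows.append((i, entry["stimulus_id"], cross[i], stimulus_duration_ms,
                     inter_trial_gap_ms, stim_onset, entry["category"]))
        onset = stim_onset + stimulus_duration_ms + inter_trial_gap_ms
    df = pd.DataFrame(rows, columns=[
        "trial_id", "stimulus_id", "cross_duration_ms", "stimulus_duration_ms",
        "inter_trial_gap_ms", "stimulus_onset_ms", "condition"])
    return TrialSchedule(df)


# ---------------------------------------------------------------------------
# ROI layout (geometric stand-in for manually segmented face masks)
# ---------------------------------------------------------------------------

_ROI_LABELS = {1: "forehead", 2: "brows", 3: "corrugator", 4: "eyes",
               5: "nose", 6: "mouth", 7: "chin"}


def default_roi_layout(deg_per_px: float = 0.25) -> ROILayout:
    """Geometric 7-region face layout on a 30 x 40 degree image.

    Synthetic stand-in for hand-segmented face masks: rectangles/ellipses
    for forehead, brows, corrugator, eyes, nose, mouth and chin, centred on
    the screen centre (where the fixation cross and the nose sit).
    """
    width_deg, height_deg = 30.0, 40.0
    ncol = int(round(width_deg / deg_per_px))
    nrow = int(round(height_deg / deg_per_px))
    xs = (np.arange(ncol) + 0.5) * deg_per_px - width_deg / 2
    ys = (np.arange(nrow) + 0.5) * deg_per_px - height_deg / 2
    X, Y = np.meshgrid(xs, ys)  # y increases downward
    labels = np.zeros((nrow, ncol), dtype=np.int16)

    face = (X / 9.0) ** 2 + (Y / 13.0) ** 2 <= 1.0
    labels[face & (Y >= -12) & (Y < -7)] = 1                              # forehead
    labels[((np.abs(X) >= 2) & (np.abs(X) <= 6)) & (Y >= -6.5) & (Y < -5)] = 2   # brows
    labels[(np.abs(X) < 2) & (Y >= -6.5) & (Y < -4.5)] = 3                # corrugator
    labels[((np.abs(X) >= 1.5) & (np.abs(X) <= 6.5)) & (Y >= -4.5) & (Y < -2.5)] = 4  # eyes
    labels[(np.abs(X) <= 2) & (Y >= -2.5) & (Y <= 2.5)] = 5               # nose
    labels[(np.abs(X) <= 4.5) & (Y >= 3.5) & (Y <= 6.5)] = 6              # mouth
    labels[face & (np.abs(X) <= 3) & (Y >= 8)] = 7                        # chin

    legend = {0: "out", **_ROI_LABELS}
    origin = (xs[0], ys[0])
    return ROILayout(labels, legend, deg_per_px, origin)


# ---------------------------------------------------------------------------
# Scanpath simulation
# ---------------------------------------------------------------------------

def _normalized(p: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(p.values()))
    return {k: v / total for k, v in p.items()}


#: Rank-wise ROI landing probabilities (fractions of fixations per region),
#: matching the observed first/second-fixation distributions over six regions.
DEFAULT_LANDING_RANK1 = _normalized({
    "brows": 1.66, "eyes": 37.2, "corrugator": 3.85,
    "nose": 42.9, "mouth": 9.51, "out": 4.17,
})
DEFAULT_LANDING_RANK2 = _normalized({
    "brows": 1.67, "eyes": 46.7, "corrugator": 3.76,
    "nose": 33.0, "mouth": 12.5, "out": 1.89,
})


@dataclass(frozen=True)
class ScanpathParams:
    """Tunable scanpath model.

    Fixation durations are log-normal (parameterised by mean/SD in ms); the
    first fixation is drawn shorter than later ones so that the rank-2 onset
    lands near 500 ms while the whole-trial mean duration stays near 300 ms.
    After each fixation the exploration terminates with probability
    ``p_terminate`` (geometric stopping), which sets the mean number of
    fixations per trial below the value a back-to-back chain would produce.
    """

    first_latency_mean_ms: float = 250.0
    first_latency_sd_ms: float = 35.0
    first_fix_duration_mean_ms: float = 212.0
    first_fix_duration_sd_ms: float = 70.0
    fix_duration_mean_ms: float = 365.0
    fix_duration_sd_ms: float = 110.0
    p_terminate: float = 0.055
    landing_by_rank: tuple[Mapping[str, float], ...] = (
        DEFAULT_LANDING_RANK1, DEFAULT_LANDING_RANK2)
    min_first_latency_ms: float = 80.0
    min_fix_duration_ms: float = 50.0
    min_saccade_deg: float = 1.0
    saccade_duration_intercept_ms: float = 21.0   # main-sequence duration model
    saccade_duration_slope_ms_per_deg: float = 2.2

    def landing(self, rank: int) -> Mapping[str, float]:
        idx = min(rank, len(self.landing_by_rank)) - 1
        return self.landing_by_rank[idx]


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _check_probs(p: Mapping[str, float]) -> None:
    if abs(sum(p.values()) - 1.0) > 1e-9:
        raise ValueError("landing probabilities must sum to 1")


def _sample_roi_position(rng: np.random.Generator, roi: str,
                         pixels: Mapping[str, np.ndarray],
                         layout: ROILayout) -> tuple[float, float]:
    rows_cols = pixels[roi]
    i = rng.integers(len(rows_cols))
    r, c = rows_cols[i]
    x = layout.origin_deg[0] + c * layout.deg_per_px
    y = layout.origin_deg[1] + r * layout.deg_per_px
    # sub-pixel jitter keeps positions continuous
    x += rng.uniform(-0.5, 0.5) * layout.deg_per_px
    y += rng.uniform(-0.5, 0.5) * layout.deg_per_px
    return x, y


def simulate_scanpath(
    schedule: TrialSchedule,
    roi_layout: ROILayout | None = None,
    params: ScanpathParams | None = None,
    seed: int = 0,
) -> EventStream:
    """Simulate a fixation/saccade scanpath for every trial of a schedule.

    Within each 2-s stimulus window the output alternates
    saccade -> fixation -> saccade -> fixation ... (the initial saccade leaves
    the fixation cross); each fixation carries rank, ROI label, duration and
    position, each saccade amplitude and orientation. A stimulus event is
    emitted per trial. Exploration may terminate before the window ends.
    """
    layout = roi_layout if roi_layout is not None else default_roi_layout()
    params = params if params is not None else ScanpathParams()
    for p in params.landing_by_rank:
        _check_probs(p)

    # precompute pixel lists per ROI once
    label_names = {v: k for k, v in layout.legend.items()}
    pixels: dict[str, np.ndarray] = {}
    for name, lab in label_names.items():
        rc = np.argwhere(layout.labels == lab)
        if len(rc):
            pixels[name] = rc

    rows: list[tuple] = []
    for _, trial in schedule.trials.iterrows():
        tid = trial["trial_id"]
        rng = np.random.default_rng([seed, 303, int(tid)])
        stim_on = float(trial["stimulus_onset_ms"])
        stim_dur = float(trial["stimulus_duration_ms"])
        stim_end = stim_on + stim_dur
        rows.append((tid, "stimulus", stim_on, stim_dur,
                     np.nan, "", np.nan, np.nan, np.nan, np.nan))
        if stim_dur <= 0:
            continue

        pos = (0.0, 0.0)  # gaze parked on the cross at stimulus onset
        rank = 1

        def draw_target(rank_: int, from_pos: tuple[float, float]):
            probs = params.landing(rank_)
            names = sorted(probs)
            roi_ = str(rng.choice(names, p=[probs[n] for n in names]))
            # resample sub-amplitude landings: refixations below ~1 degree
            # would be undetectable and are not modelled
            for _ in range(20):
                new_pos_ = _sample_roi_position(rng, roi_, pixels, layout)
                dx, dy = new_pos_[0] - from_pos[0], new_pos_[1] - from_pos[1]
                amp_ = math.hypot(dx, dy)
                if amp_ >= params.min_saccade_deg:
                    break
            orient_ = math.degrees(math.atan2(-dy, dx))  # y grows downward
            sdur_ = (params.saccade_duration_intercept_ms
                     + params.saccade_duration_slope_ms_per_deg * amp_)
            return roi_, new_pos_, amp_, orient_, sdur_

        roi, new_pos, amp, orient, sacc_dur = draw_target(1, pos)
        t_fix = stim_on + max(params.min_first_latency_ms,
                              rng.normal(params.first_latency_mean_ms,
                                         params.first_latency_sd_ms))
        sacc_on = t_fix - sacc_dur
        while t_fix < stim_end:
            if sacc_on >= stim_on:
                rows.append((tid, "saccade", sacc_on, sacc_dur,
                             np.nan, "", amp, orient, pos[0], pos[1]))
            if rank == 1:
                dur = _lognormal(rng, params.first_fix_duration_mean_ms,
                                 params.first_fix_duration_sd_ms)
            else:
                dur = _lognormal(rng, params.fix_duration_mean_ms,
                                 params.fix_duration_sd_ms)
            dur = max(dur, params.min_fix_duration_ms)
            truncated = t_fix + dur >= stim_end
            if truncated:
                dur = stim_end - t_fix
            rows.append((tid, "fixation", t_fix, dur, rank, roi,
                         np.nan, np.nan, new_pos[0], new_pos[1]))
            pos = new_pos
            if truncated or rng.random() < params.p_terminate:
                break
            rank += 1
            roi, new_pos, amp, orient, sacc_dur = draw_target(rank, pos)
            sacc_on = t_fix + dur
            t_fix = sacc_on + sacc_dur
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventStream(frame)


# ---------------------------------------------------------------------------
# Gaze rendering (inverse of the detector, for detector testing)
# ---------------------------------------------------------------------------

def render_gaze_samples(
    events: EventStream,
    rate: float = 1000.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    span_ms: tuple[float, float] | None = None,
) -> GazeRecording:
    """Render a sampled gaze trace from a fixation/saccade event stream.

    Gaze is piecewise-constant at fixation positions, with ballistic
    (cubic smoothstep) transitions during saccades and optional Gaussian
    positional jitter.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    fix = events.fixations().sort_values("onset_ms")
    sac = events.saccades().sort_values("onset_ms")
    if span_ms is None:
        all_ev = events.frame[events.frame["event_type"] != "stimulus"]
        if len(all_ev) == 0:
            raise ValueError("no fixation/saccade events to render")
        t0 = float(all_ev["onset_ms"].min())
        t1 = float((all_ev["onset_ms"] + all_ev["duration_ms"]).max())
    else:
        t0, t1 = span_ms
    dt = 1000.0 / rate
    time = t0 + np.arange(int(math.floor((t1 - t0) / dt)) + 1) * dt
    x = np.empty_like(time)
    y = np.empty_like(time)

    # segment list: (start, end, kind, payload)
    segs: list[tuple[float, float, str, tuple]] = []
    for _, f in fix.iterrows():
        segs.append((f["onset_ms"], f["onset_ms"] + f["duration_ms"], "fix",
                     (f["x_deg"], f["y_deg"])))
    fix_list = fix.reset_index(drop=True)
    for _, s in sac.iterrows():
        s_end = s["onset_ms"] + s["duration_ms"]
        start_pos = (s["x_deg"], s["y_deg"])
        after = fix_list[fix_list["onset_ms"] >= s["onset_ms"] - 1e-9]
        end_pos = ((after.iloc[0]["x_deg"], after.iloc[0]["y_deg"])
                   if len(after) else start_pos)
        segs.append((s["onset_ms"], s_end, "sac", (start_pos, end_pos)))
    segs.sort(key=lambda s: s[0])

    # default position before/after/between segments: hold previous target
    cur = segs[0][3] if segs and segs[0][2] == "fix" else (
        segs[0][3][0] if segs else (0.0, 0.0))
    xpos = np.full_like(time, float(cur[0]))
    ypos = np.full_like(time, float(cur[1]))
    for start, end, kind, payload in segs:
        sel = (time >= start - 1e-9) & (time <= end + 1e-9)
        if kind == "fix":
            px, py = payload
            xpos[sel] = px
            ypos[sel] = py
            hold = (px, py)
        else:
            (x0, y0), (x1, y1) = payload
            u = np.clip((time[sel] - start) / max(end - start, dt), 0.0, 1.0)
            w = u * u * (3.0 - 2.0 * u)
            xpos[sel] = x0 + (x1 - x0) * w
            ypos[sel] = y0 + (y1 - y0) * w
            hold = (x1, y1)
        after = time > end + 1e-9
        xpos[after] = hold[0]
        ypos[after] = hold[1]
    x, y = xpos, ypos
    if jitter_sd > 0:
        rng = np.random.default_rng([seed, 404])
        x = x + rng.normal(0.0, jitter_sd, size=x.shape)
        y = y + rng.normal(0.0, jitter_sd, size=y.shape)
    return GazeRecording(time, x, y, rate)


# ---------------------------------------------------------------------------
# Kernels and EEG synthesis
# ---------------------------------------------------------------------------

def _bump_sum(lags: np.ndarray, bumps: Sequence[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(lags, dtype=float)
    for amp, mu, sd in bumps:
        out += amp * np.exp(-0.5 * ((lags - mu) / sd) ** 2)
    return out


def make_default_kernels(
    rate: float = 500.0,
    effect_spec: Sequence[Modulation] = (),
) -> KernelSet:
    """Plausible evoked-potential kernels with extrema inside the standard
    component latency windows (P1 90-130, N170 140-180, P2-P3 200-350,
    LPP 400-600 ms for the stimulus kernel; lambda 20-110 and P2 180-400 ms
    for the fixation kernels)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    dt = 1000.0 / rate

    def axis(lo: float, hi: float) -> np.ndarray:
        return np.arange(round(lo / dt), round(hi / dt) + 1) * dt

    s_lags = axis(0, 800)
    s = Waveform(s_lags, _bump_sum(s_lags, [
        (4.0, 110, 12), (-5.0, 160, 14), (5.0, 270, 45), (3.0, 480, 70)]))
    f_lags = axis(0, 600)
    fp1 = Waveform(f_lags, _bump_sum(f_lags, [
        (6.0, 60, 15), (-2.0, 130, 25), (3.0, 250, 50)]))
    fp2plus = Waveform(f_lags, _bump_sum(f_lags, [
        (4.0, 60, 15), (-1.2, 130, 25), (1.8, 250, 50)]))
    sp_lags = axis(-50, 100)
    sp = Waveform(sp_lags, _bump_sum(sp_lags, [(2.5, 5, 8), (-1.5, 28, 10)]))
    return KernelSet(s, fp1, fp2plus, sp, tuple(effect_spec))


def _modulated(base: Waveform, mods: Sequence[Modulation], target: str,
               condition: str | None, site: str) -> np.ndarray:
    data = base.data
    extra = np.zeros_like(data)
    for m in mods:
        if m.target != target or m.site != site:
            continue
        if condition is not None and m.condition != condition:
            continue
        lo, hi = m.window_ms
        extra[(base.lags_ms >= lo) & (base.lags_ms <= hi)] += m.offset_uv
    return data + extra


def one_over_f_noise(n: int, rate: float, model: NoiseModel,
                     stream: Sequence[int]) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit-variance
    shaped then scaled to ``amplitude_sd`` RMS."""
    if model.amplitude_sd == 0:
        return np.zeros(n)
    rng = np.random.default_rng([model.seed, *stream])
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-model.spectrum_exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped / rms * model.amplitude_sd


def simulate_eeg(
    events: EventStream,
    kernels: KernelSet,
    noise: NoiseModel,
    channels: Sequence[str],
    rate: float = 500.0,
    condition_by_trial: Mapping | None = None,
    duration_ms: float | None = None,
) -> ContinuousEEG:
    """Superpose event-locked kernels into a continuous multichannel EEG.

    Each channel is the sum over events of the class-appropriate kernel
    shifted to the event's timestamp (stimulus -> s, rank-1 fixation -> fp1,
    rank-2+ fixation -> fp2plus, saccade -> sp), plus per-(condition, site)
    modulations, plus one independent 1/f noise draw per channel.
    """
    if abs(kernels.rate - rate) > 1e-6:
        raise ValueError("kernel sampling rate must equal the synthesis rate")
    dt = 1000.0 / rate
    frame = events.frame
    if duration_ms is None:
        end = float((frame["onset_ms"] + frame["duration_ms"].fillna(0)).max())
        duration_ms = end + 1000.0
    n = int(round(duration_ms / dt))
    cond = dict(condition_by_trial) if condition_by_trial else {}

    data = np.zeros((n, len(channels)))
    mods = kernels.modulations
    for ci, ch in enumerate(channels):
        sig = data[:, ci]
        for _, ev in frame.iterrows():
            etype = ev["event_type"]
            if etype == "stimulus":
                base, target = kernels.s, "s"
            elif etype == "fixation":
                if int(ev["rank"]) == 1:
                    base, target = kernels.fp1, "fp1"
                else:
                    base, target = kernels.fp2plus, "fp2plus"
            elif etype == "saccade":
                base, target = kernels.sp, "sp"
            else:
                raise ValueError(f"unknown event class {etype!r}")
            kdata = (_modulated(base, mods, target, cond.get(ev["trial_id"]), ch)
                     if mods else base.data)
            start = int(round(ev["onset_ms"] / dt)) + int(round(base.lags_ms[0] / dt))
            lo = max(start, 0)
            hi = min(start + len(kdata), n)
            if hi > lo:
                sig[lo:hi] += kdata[lo - start:hi - start]
        if noise.amplitude_sd > 0:
            sig += one_over_f_noise(n, rate, noise, stream=[ci])
    return ContinuousEEG(data, rate, tuple(channels), reference="synthetic")
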