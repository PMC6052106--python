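"""EEG preprocessing: filtering, re-referencing, epoching, baseline
correction, epoch/participant rejection and virtual-electrode pooling.

Timestamps are converted to sample indices with round-half-to-even; epoch
windows are inclusive at both ends, so a [-200, 2000] ms window at 500 Hz
yields 1101 samples.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EpochSet

#: The seven scalp regions pooled into virtual electrodes (10-20 labels).
DEFAULT_VIRTUAL_ELECTRODES: dict[str, tuple[str, ...]] = {
    "left_frontal": ("F3", "F5", "F7", "FC5", "FC3"),
    "right_frontal": ("F4", "F6", "F8", "FC6", "FC4"),
    "left_centro_parietal": ("C3", "C5", "T7", "CP3", "CP5"),
    "right_centro_parietal": ("C4", "C6", "T8", "CP4", "CP6"),
    "left_parieto_occipital": ("P3", "P5", "P7", "PO3", "PO7"),
    "right_parieto_occipital": ("P4", "P6", "P8", "PO4", "PO8"),
    "median_occipital": ("POz", "O1", "Oz", "O2"),
}


def filter_eeg(
    eeg: ContinuousEEG,
    band: tuple[float, float] = (1.0, 70.0),
    notch: float | None = 50.0,
) -> ContinuousEEG:
    """Zero-phase band-pass (default 1-70 Hz) plus notch (default 50 Hz)."""
    import mne

    lo, hi = band
    nyq = eeg.rate / 2.0
    if hi >= nyq or (notch is not None and notch >= nyq):
        raise ValueError("band edge / notch must lie below Nyquist")
    data = np.ascontiguousarray(eeg.data.T)  # mne expects channels x time
    data = mne.filter.filter_data(data, eeg.rate, l_freq=lo, h_freq=hi,
                                  verbose="error")
    if notch is not None:
        data = mne.filter.notch_filter(data, eeg.rate, freqs=notch,
                                       verbose="error")
    return ContinuousEEG(data.T, eeg.rate, eeg.ch_names, eeg.reference)


def rereference_average(eeg: ContinuousEEG) -> ContinuousEEG:
    """Re-reference to the average of all channels (per-sample mean -> 0)."""
    if eeg.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = eeg.data - eeg.data.mean(axis=1, keepdims=True)
    return ContinuousEEG(data, eeg.rate, eeg.ch_names, reference="average")


def _ms_to_sample(ms: float, rate: float) -> int:
    # round-half-to-even, matching numpy's rounding
    return int(np.round(ms * rate / 1000.0))


def epoch_and_baseline(
    eeg: ContinuousEEG,
    onsets_ms: Sequence[float],
    window_ms: tuple[float, float] = (-200.0, 2000.0),
    baseline_ms: tuple[float, float] | None = (-200.0, 0.0),
    metadata: pd.DataFrame | None = None,
) -> tuple[EpochSet, list[int]]:
    """Cut stimulus-locked epochs and subtract the per-epoch baseline mean.

    Returns the epoch set and the indices of onsets skipped because their
    window fell outside the recording.
    """
    lo_s = _ms_to_sample(window_ms[0], eeg.rate)
    hi_s = _ms_to_sample(window_ms[1], eeg.rate)
    n_t = hi_s - lo_s + 1  # both endpoints inclusive
    times_ms = np.arange(lo_s, hi_s + 1) * 1000.0 / eeg.rate

    epochs = []
    kept_rows = []
    skipped: list[int] = []
    for i, onset in enumerate(onsets_ms):
        c = _ms_to_sample(onset, eeg.rate)
        a, b = c + lo_s, c + hi_s
        if a < 0 or b >= eeg.n_samples:
            skipped.append(i)
            continue
        epochs.append(eeg.data[a:b + 1, :])
        kept_rows.append(i)
    data = (np.stack(epochs, axis=0) if epochs
            else np.empty((0, n_t, eeg.n_channels)))
    if metadata is None:
        metadata = pd.DataFrame({"onset_ms": list(onsets_ms)})
    meta = metadata.iloc[kept_rows].reset_index(drop=True)
    out = EpochSet(data, times_ms, eeg.rate, eeg.ch_names, meta,
                   baseline_ms=baseline_ms)
    if baseline_ms is not None:
        out = baseline_correct(out, baseline_ms)
    return out, skipped


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the mean over the baseline window, per epoch and channel."""
    sel = (epochs.times_ms >= baseline_ms[0]) & (epochs.times_ms <= baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    means = epochs.data[:, sel, :].mean(axis=1, keepdims=True)
    return EpochSet(epochs.data - means, epochs.times_ms, epochs.rate,
                    epochs.ch_names, epochs.metadata, baseline_ms=baseline_ms)


def reject_epochs(
    epochs: EpochSet,
    k: float = 3.0,
    min_fixations: int = 2,
    channel_reduce: str = "mean",
) -> tuple[EpochSet, pd.DataFrame]:
    """Reject epochs by variance (mean + k*SD across epochs, single pass)
    and by fixation count (< ``min_fixations`` during the trial).

    Epoch variance is the time-variance per channel reduced over channels by
    the unweighted mean (or max if ``channel_reduce='max'``). Returns the
    surviving epochs and a per-epoch report with the rejection reasons.
    """
    n = epochs.n_epochs
    var_ch = epochs.data.var(axis=1, ddof=1)  # epoch x channel
    reduce = {"mean": np.mean, "max": np.max}[channel_reduce]
    var = reduce(var_ch, axis=1) if n else np.empty(0)

    var_reject = np.zeros(n, dtype=bool)
    threshold = np.nan
    if n >= 2:
        threshold = var.mean() + k * var.std(ddof=1)
        var_reject = var > threshold
    elif n:
        warnings.warn("fewer than 2 epochs: variance rule skipped")

    if "n_fixations" in epochs.metadata.columns:
        fix_counts = epochs.metadata["n_fixations"].to_numpy()
    else:
        fix_counts = np.full(n, np.iinfo(np.int32).max)
    fix_reject = fix_counts < min_fixations

    reasons = []
    for v, f in zip(var_reject, fix_reject):
        r = []
        if v:
            r.append("variance")
        if f:
            r.append("too_few_fixations")
        reasons.append("+".join(r) if r else "")
    report = pd.DataFrame({
        "epoch": np.arange(n), "variance": var, "threshold": threshold,
        "n_fixations": fix_counts, "rejected": var_reject | fix_reject,
        "reason": reasons,
    })
    keep = ~(var_reject | fix_reject)
    return epochs.select(keep), report


def exclude_participants(
    counts: pd.DataFrame,
    min_epochs: int = 5,
) -> pd.Series:
    """Inclusion mask: a participant is kept iff every condition has at
    least ``min_epochs`` epochs. ``counts`` is participants x conditions."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("epoch counts must be nonnegative")
    return (counts >= min_epochs).all(axis=1)


def pool_virtual_electrodes(
    epochs: EpochSet,
    region_map: Mapping[str, Sequence[str]] | None = None,
) -> EpochSet:
    """Average channel groups into virtual electrodes (default: the seven
    standard scalp regions)."""
    region_map = dict(DEFAULT_VIRTUAL_ELECTRODES if region_map is None else region_map)
    idx = {name: i for i, name in enumerate(epochs.ch_names)}
    for region, members in region_map.items():
        for ch in members:
            if ch not in idx:
                raise ValueError(f"channel {ch!r} (region {region!r}) not present")
    pooled = np.stack(
        [epochs.data[:, :, [idx[ch] for ch in members]].mean(axis=2)
         for members in region_map.values()],
        axis=2,
    )
    return EpochSet(pooled, epochs.times_ms, epochs.rate,
                    tuple(region_map.keys()), epochs.metadata,
                    baseline_ms=epochs.baseline_ms)
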