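"""Overlap-corrected evoked-potential estimation.

Classical averaging assumes one evoked response per epoch; under free
viewing the stimulus response s(t) superposes with fixation- and
saccade-locked responses, so the average is biased. The GLM deconvolution
estimates all four kernels jointly: a sparse stick-function design matrix
places a unit regressor at every (event, lag) pair and ordinary least
squares on the concatenated epochs separates the overlapping responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse

from .containers import EpochSet, EventStream, KernelSet, Waveform

#: Default estimation windows (ms relative to the locking event). The
#: stimulus response is modelled out to 800 ms (stimulus-evoked activity
#: lasts about 700 ms), fixation responses to 600 ms, the saccadic response
#: over a short peri-saccadic window.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "s": (-200.0, 800.0),
    "fp1": (-200.0, 600.0),
    "fp2plus": (-200.0, 600.0),
    "sp": (-50.0, 100.0),
}

KERNEL_CLASSES = ("s", "fp1", "fp2plus", "sp")


class RankDeficientDesignWarning(UserWarning):
    pass


class IdentifiabilityWarning(UserWarning):
    pass


def average_erp(epochs: EpochSet) -> Waveform:
    """Classical average: per-sample unweighted mean across epochs."""
    if epochs.n_epochs == 0:
        raise ValueError("cannot average zero epochs")
    return Waveform(epochs.times_ms, epochs.data.mean(axis=0))


def _event_class(row: pd.Series) -> str:
    if row["event_type"] == "stimulus":
        return "s"
    if row["event_type"] == "saccade":
        return "sp"
    return "fp1" if int(row["rank"]) == 1 else "fp2plus"


@dataclass(frozen=True)
class DesignMatrix:
    """Sparse 0/1 stick-function design over concatenated epochs."""

    X: scipy.sparse.csr_matrix
    col_map: pd.DataFrame          # columns: klass, lag_sample, lag_ms
    n_epochs: int
    n_samples_per_epoch: int
    empty_columns: np.ndarray      # lags truncated at every event

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def lags_ms(self, klass: str) -> np.ndarray:
        return self.col_map.loc[self.col_map["klass"] == klass, "lag_ms"].to_numpy()


def build_design_matrix(
    events: EventStream,
    trial_ids: Sequence,
    epoch_times_ms: np.ndarray,
    rate: float,
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> DesignMatrix:
    """Build the stick-function regressor matrix for the listed epochs.

    ``trial_ids`` gives, per epoch, the trial whose events populate it; the
    per-trial stimulus event anchors the epoch (epoch sample 0 is the first
    sample of ``epoch_times_ms``). For each event of class c at epoch sample
    t0 and each lag l in c's window, entry (epoch_offset + t0 + l, column
    (c, l)) is set to 1; lags falling outside the epoch are omitted.
    """
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)
    for k in windows:
        if k not in KERNEL_CLASSES:
            raise ValueError(f"unknown kernel class {k!r}")
    dt = 1000.0 / rate
    T = len(epoch_times_ms)
    t_lo = int(np.round(epoch_times_ms[0] / dt))

    # column layout: classes in canonical order, lags ascending
    col_rows = []
    offsets: dict[str, tuple[int, int]] = {}
    start = 0
    for klass in KERNEL_CLASSES:
        if klass not in windows:
            continue
        lo, hi = windows[klass]
        lo_s, hi_s = int(np.round(lo / dt)), int(np.round(hi / dt))
        lags = np.arange(lo_s, hi_s + 1)
        offsets[klass] = (start, lo_s)
        for ls in lags:
            col_rows.append((klass, ls, ls * dt))
        start += len(lags)
    col_map = pd.DataFrame(col_rows, columns=["klass", "lag_sample", "lag_ms"])
    n_cols = len(col_map)

    stim = events.stimuli().set_index("trial_id")["onset_ms"]
    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    for e_i, tid in enumerate(trial_ids):
        if tid not in stim.index:
            raise ValueError(f"no stimulus event for trial {tid!r}")
        onset0 = float(stim.loc[tid])
        trial_events = events.frame[events.frame["trial_id"] == tid]
        for _, ev in trial_events.iterrows():
            klass = _event_class(ev)
            if klass not in offsets:
                continue
            col0, lo_s = offsets[klass]
            n_lags = ((col_map["klass"] == klass).sum())
            # round absolute times independently, matching how epochs are cut
            t0 = (int(np.round(ev["onset_ms"] / dt))
                  - int(np.round(onset0 / dt)) - t_lo)
            lag_rel = np.arange(n_lags) + lo_s
            r = t0 + lag_rel
            valid = (r >= 0) & (r < T)
            rows_idx.append(e_i * T + r[valid])
            cols_idx.append(col0 + np.flatnonzero(valid))
    if rows_idx:
        rows = np.concatenate(rows_idx)
        cols = np.concatenate(cols_idx)
    else:
        rows = np.empty(0, dtype=int)
        cols = np.empty(0, dtype=int)
    X = scipy.sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(trial_ids) * T, n_cols),
    ).tocsr()
    # duplicate (row, col) pairs from coincident events collapse to 1
    X.data = np.minimum(X.data, 1.0)
    empty = np.flatnonzero(np.asarray(X.sum(axis=0)).ravel() == 0)
    return DesignMatrix(X, col_map, len(trial_ids), T, empty)


@dataclass(frozen=True)
class KernelEstimates:
    """Per-class kernel estimates (lags x channels) plus diagnostics."""

    estimates: dict[str, Waveform]
    ch_names: tuple[str, ...]
    s_avg: Waveform | None = None
    condition: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for klass, wf in self.estimates.items():
            data = np.atleast_2d(wf.data.T).T
            for ci, ch in enumerate(self.ch_names):
                for lag, amp in zip(wf.lags_ms, data[:, ci]):
                    rows.append((klass, ch, lag, amp))
        return pd.DataFrame(rows, columns=["class", "channel", "lag_ms", "amplitude_uv"])


def glm_estimate(
    epochs: EpochSet,
    events: EventStream,
    windows: Mapping[str, tuple[float, float]] | None = None,
    ridge: float = 0.0,
    condition: str | None = None,
    compute_condition_number: bool = True,
) -> KernelEstimates:
    """Jointly estimate s, fp1, fp2plus and sp by least squares.

    Coefficients minimise the squared residual of the concatenated epochs
    against the stick-function design; rank-deficient designs fall back to
    the minimum-norm solution with a warning. An identifiability warning is
    emitted when first-fixation latencies are nearly constant (the s and fp1
    regressor blocks become collinear). ``ridge`` adds an optional Tikhonov
    penalty (0 = pure OLS, the faithful default).
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs")
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)

    trial_ids = epochs.metadata["trial_id"].tolist()
    sub = events.frame[events.frame["trial_id"].isin(trial_ids)]
    sub_stream = EventStream(sub)

    # drop classes with no events (their columns would be all-zero)
    present = set()
    for _, ev in sub.iterrows():
        present.add(_event_class(ev))
    dropped = [k for k in windows if k not in present]
    for k in dropped:
        warnings.warn(f"kernel class {k!r} has no events; dropped from the model")
        windows.pop(k)
    if not windows:
        raise ValueError("design is all-zero: no modeled events")

    _check_identifiability(sub_stream, rate=epochs.rate)

    design = build_design_matrix(sub_stream, trial_ids, epochs.times_ms,
                                 epochs.rate, windows)
    X = design.X
    n_rows, n_cols = X.shape
    Y = epochs.data.reshape(epochs.n_epochs * design.n_samples_per_epoch,
                            len(epochs.ch_names))
    XtX = np.asarray((X.T @ X).todense())
    if ridge > 0:
        XtX = XtX + ridge * np.eye(n_cols)
    XtY = X.T @ Y

    cond = np.nan
    if compute_condition_number:
        eig = scipy.linalg.eigvalsh(XtX)
        pos = eig[eig > max(eig.max(), 1.0) * 1e-14]
        cond = float(np.sqrt(eig.max() / pos.min())) if len(pos) else np.inf

    beta, rank = _solve_normal_equations(XtX, XtY)
    if rank < n_cols:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {n_cols}); "
            "returning the minimum-norm least-squares solution",
            RankDeficientDesignWarning,
        )

    resid = Y - X @ beta
    diagnostics = {
        "residual_variance": float(np.mean(resid ** 2)),
        "condition_number": cond,
        "rank": int(rank),
        "n_columns": int(n_cols),
        "dropped_classes": dropped,
        "n_empty_columns": int(len(design.empty_columns)),
        "ridge": ridge,
    }
    estimates = {}
    for klass in windows:
        sel = (design.col_map["klass"] == klass).to_numpy()
        estimates[klass] = Waveform(design.lags_ms(klass), beta[sel, :])
    return KernelEstimates(estimates, epochs.ch_names,
                           s_avg=average_erp(epochs),
                           condition=condition, diagnostics=diagnostics)


def _solve_normal_equations(XtX: np.ndarray, XtY: np.ndarray) -> tuple[np.ndarray, int]:
    """Solve XtX b = XtY; Cholesky when well posed, else min-norm lstsq.

    For a consistent normal system the minimum-norm solution of the normal
    equations coincides with the pseudo-inverse (minimum-norm least-squares)
    solution of the original problem.
    """
    try:
        c, low = scipy.linalg.cho_factor(XtX)
        # treat near-singular systems as rank deficient
        diag = np.diag(c)
        if np.min(diag) < 1e-7 * np.max(diag):
            raise np.linalg.LinAlgError
        return scipy.linalg.cho_solve((c, low), XtY), XtX.shape[0]
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        beta, _, rank, _ = scipy.linalg.lstsq(XtX, XtY,
                                              cond=1e-10, lapack_driver="gelsd")
        return beta, rank


def _check_identifiability(events: EventStream, rate: float = 1000.0,
                           min_sd_samples: float = 2.0) -> None:
    fix = events.fixations()
    stim = events.stimuli().set_index("trial_id")["onset_ms"]
    first = fix[fix["rank"] == 1]
    if len(first) < 2:
        return
    lat = first["onset_ms"].to_numpy() - stim.reindex(first["trial_id"]).to_numpy()
    sd_ms = float(np.std(lat, ddof=1))
    # jitter below ~2 samples makes the s and fp1 blocks near-collinear
    if sd_ms < min_sd_samples * 1000.0 / rate:
        warnings.warn(
            f"first-fixation latency jitter SD {sd_ms:.2f} ms is very small; "
            "stimulus and first-fixation regressors are nearly collinear",
            IdentifiabilityWarning,
        )


def averaging_bias(
    kernels: KernelSet,
    events: EventStream,
    epoch_times_ms: np.ndarray,
    rate: float,
    trial_ids: Sequence | None = None,
    baseline_ms: tuple[float, float] | None = None,
) -> Waveform:
    """Expected distortion of the averaged ERP from overlapping responses.

    Returns the mean over epochs of every non-stimulus kernel shifted to its
    event latency and restricted to the epoch window, so that
    E[s_avg] = s + bias (both baseline-corrected if ``baseline_ms`` given).
    """
    dt = 1000.0 / rate
    T = len(epoch_times_ms)
    t_lo = int(np.round(epoch_times_ms[0] / dt))
    stim = events.stimuli().set_index("trial_id")["onset_ms"]
    if trial_ids is None:
        trial_ids = stim.index.tolist()
    acc = np.zeros(T)
    for tid in trial_ids:
        onset0 = float(stim.loc[tid])
        trial_events = events.frame[
            (events.frame["trial_id"] == tid)
            & (events.frame["event_type"] != "stimulus")]
        for _, ev in trial_events.iterrows():
            klass = _event_class(ev)
            k = kernels.kernel(klass)
            t0 = (int(np.round(ev["onset_ms"] / dt))
                  - int(np.round(onset0 / dt)) - t_lo)
            start = t0 + int(np.round(k.lags_ms[0] / dt))
            lo, hi = max(start, 0), min(start + len(k.data), T)
            if hi > lo:
                acc[lo:hi] += k.data[lo - start:hi - start]
    bias = acc / max(len(trial_ids), 1)
    if baseline_ms is not None:
        sel = (epoch_times_ms >= baseline_ms[0]) & (epoch_times_ms <= baseline_ms[1])
        bias = bias - bias[sel].mean()
    return Waveform(epoch_times_ms, bias)
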