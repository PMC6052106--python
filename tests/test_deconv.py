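"""Design matrix construction, OLS kernel estimation and averaging bias."""

import warnings

import numpy as np
import pandas as pd
import pytest

import fixglm as fg
from fixglm.deconv import (IdentifiabilityWarning, RankDeficientDesignWarning,
                           build_design_matrix)

RATE = 500.0


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def _epochset(data):
    meta = pd.DataFrame({"trial_id": np.arange(data.shape[0]),
                         "condition": "neutral", "n_fixations": 5})
    times = np.arange(data.shape[1]) * 1000.0 / RATE
    chans = tuple(f"c{i}" for i in range(data.shape[2]))
    return fg.EpochSet(data, times, RATE, chans, meta)


def test_average_identity_cancellation_and_bruteforce():
    w = np.random.default_rng(0).normal(size=(1, 50, 2))
    same = _epochset(np.tile(w, (5, 1, 1)))
    np.testing.assert_allclose(fg.average_erp(same).data, w[0], atol=1e-12)

    pair = _epochset(np.concatenate([w, -w], axis=0))
    np.testing.assert_allclose(fg.average_erp(pair).data, 0.0, atol=1e-12)

    rng = np.random.default_rng(1)
    data = rng.normal(size=(10, 30, 2))
    acc = np.zeros((30, 2))
    for i in range(10):
        acc += data[i]
    np.testing.assert_allclose(fg.average_erp(_epochset(data)).data, acc / 10,
                               atol=1e-12)


def test_average_empty_rejected():
    with pytest.raises(ValueError):
        fg.average_erp(_epochset(np.empty((0, 10, 1))))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _stim_stream(onset_ms=0.0, extra_rows=()):
    rows = [(0, "stimulus", onset_ms, 2000.0, np.nan, "", np.nan, np.nan,
             np.nan, np.nan), *extra_rows]
    return fg.EventStream(pd.DataFrame(rows, columns=fg.containers.EVENT_COLUMNS))


def test_single_stick_places_consecutive_diagonal():
    # epoch starts 10 samples before the stimulus, so the stick lands at
    # epoch samples 10, 11, 12 on three consecutive s-columns
    events = _stim_stream(onset_ms=20.0)
    times = np.arange(-10, 40) * 2.0
    dm = build_design_matrix(events, [0], times, RATE, {"s": (0.0, 4.0)})
    assert dm.shape == (50, 3)
    rows, cols = dm.X.nonzero()
    assert list(rows) == [10, 11, 12]
    assert list(cols) == [0, 1, 2]


def test_design_column_count_is_sum_of_window_lengths():
    events = _stim_stream(extra_rows=[
        (0, "fixation", 250.0, 300.0, 1, "", np.nan, np.nan, 0.0, 0.0),
        (0, "saccade", 600.0, 30.0, np.nan, "", 3.0, 0.0, 0.0, 0.0),
        (0, "fixation", 630.0, 300.0, 2, "", np.nan, np.nan, 1.0, 0.0),
    ])
    times = np.arange(-100, 1000) * 2.0
    windows = {"s": (0.0, 100.0), "fp1": (0.0, 80.0),
               "fp2plus": (0.0, 60.0), "sp": (-10.0, 20.0)}
    dm = build_design_matrix(events, [0], times, RATE, windows)
    expected_cols = (51) + (41) + (31) + (16)
    assert dm.shape[1] == expected_cols


def test_design_nonzeros_match_bruteforce_count(small_simulation):
    events = small_simulation["events"]
    epochs = small_simulation["epochs"]
    dm = build_design_matrix(events, epochs.metadata["trial_id"].tolist(),
                             epochs.times_ms, RATE)
    # independent count: sum over events of non-truncated window lengths
    dt = 1000.0 / RATE
    T = len(epochs.times_ms)
    t_lo = int(round(epochs.times_ms[0] / dt))
    stim = events.stimuli().set_index("trial_id")["onset_ms"]
    total = 0
    for tid in epochs.metadata["trial_id"]:
        for _, ev in events.frame[events.frame["trial_id"] == tid].iterrows():
            if ev["event_type"] == "stimulus":
                klass = "s"
            elif ev["event_type"] == "saccade":
                klass = "sp"
            else:
                klass = "fp1" if ev["rank"] == 1 else "fp2plus"
            lo, hi = fg.DEFAULT_WINDOWS[klass]
            t0 = (int(round(ev["onset_ms"] / dt)) -
                  int(round(stim.loc[tid] / dt)) - t_lo)
            for lag in range(int(round(lo / dt)), int(round(hi / dt)) + 1):
                if 0 <= t0 + lag < T:
                    total += 1
    assert dm.X.nnz == total
    assert set(np.unique(dm.X.data)) <= {1.0}


# ---------------------------------------------------------------------------
# GLM estimation
# ---------------------------------------------------------------------------

def test_noiseless_recovery_of_all_kernels(small_simulation):
    epochs = small_simulation["epochs"]
    events = small_simulation["events"]
    kernels = small_simulation["kernels"]
    est = fg.glm_estimate(epochs, events)
    assert est.diagnostics["rank"] == est.diagnostics["n_columns"]
    for klass in ("s", "fp1", "fp2plus", "sp"):
        wf = est.estimates[klass]
        true = kernels.kernel(klass)
        sel = np.isin(np.round(wf.lags_ms, 6), np.round(true.lags_ms, 6))
        rmse = np.sqrt(np.mean((wf.data[sel, 0] - true.data) ** 2))
        assert rmse < 1e-6


def test_stimulus_only_glm_equals_average(small_simulation):
    sched = small_simulation["schedule"]
    kernels = small_simulation["kernels"]
    events = fg.EventStream(small_simulation["events"].stimuli())
    eeg = fg.simulate_eeg(events, kernels, fg.NoiseModel(1.0, 6.0, seed=3),
                          ["VE"], RATE)
    epochs, _ = fg.epoch_and_baseline(eeg, sched.trials["stimulus_onset_ms"],
                                      metadata=sched.trials[["trial_id"]])
    est = fg.glm_estimate(epochs, events, windows={"s": (-200.0, 2000.0)})
    s_avg = fg.average_erp(epochs).data[:, 0]
    np.testing.assert_allclose(est.estimates["s"].data[:, 0], s_avg, atol=1e-9)


def test_estimates_linear_in_data(small_simulation):
    epochs = small_simulation["epochs"]
    events = small_simulation["events"]
    est1 = fg.glm_estimate(epochs, events)
    doubled = fg.EpochSet(2.0 * epochs.data, epochs.times_ms, epochs.rate,
                          epochs.ch_names, epochs.metadata)
    est2 = fg.glm_estimate(doubled, events)
    for klass in est1.estimates:
        np.testing.assert_allclose(est2.estimates[klass].data,
                                   2.0 * est1.estimates[klass].data, atol=1e-8)


def test_duplicated_classes_fall_back_to_minimum_norm(small_simulation):
    epochs = small_simulation["epochs"]
    events = small_simulation["events"]
    frame = events.frame.copy()
    # force fp2plus events onto the fp1 timestamps: identical column blocks
    fix = frame["event_type"] == "fixation"
    dup = frame[fix & (frame["rank"] == 1)].copy()
    dup["rank"] = 2
    dup["onset_ms"] += 1e-9
    merged = fg.EventStream(pd.concat([frame[~(fix & (frame["rank"] > 1))],
                                       dup], ignore_index=True))
    with pytest.warns(RankDeficientDesignWarning):
        est = fg.glm_estimate(epochs, merged,
                              windows={"s": (-200.0, 800.0),
                                       "fp1": (0.0, 400.0),
                                       "fp2plus": (0.0, 400.0)})
    assert est.diagnostics["rank"] < est.diagnostics["n_columns"]
    # minimum-norm solution splits the shared response across the twins
    np.testing.assert_allclose(est.estimates["fp1"].data,
                               est.estimates["fp2plus"].data, atol=1e-6)


def test_zero_event_class_dropped_with_warning(small_simulation):
    sched = small_simulation["schedule"]
    kernels = small_simulation["kernels"]
    events = fg.EventStream(small_simulation["events"].stimuli())
    eeg = fg.simulate_eeg(events, kernels, fg.NoiseModel(amplitude_sd=0.0),
                          ["VE"], RATE)
    epochs, _ = fg.epoch_and_baseline(eeg, sched.trials["stimulus_onset_ms"],
                                      metadata=sched.trials[["trial_id"]])
    with pytest.warns(UserWarning, match="no events"):
        est = fg.glm_estimate(epochs, events)
    assert set(est.estimates) == {"s"}
    assert set(est.diagnostics["dropped_classes"]) == {"fp1", "fp2plus", "sp"}


def test_identifiability_warning_on_constant_latency(small_simulation):
    kernels = small_simulation["kernels"]
    rows = []
    for tid in range(6):
        t0 = 1000.0 + tid * 8000.0
        rows.append((tid, "stimulus", t0, 2000.0, np.nan, "", np.nan, np.nan,
                     np.nan, np.nan))
        rows.append((tid, "fixation", t0 + 250.0, 300.0, 1, "", np.nan,
                     np.nan, 0.0, 0.0))
    events = fg.EventStream(pd.DataFrame(rows, columns=fg.containers.EVENT_COLUMNS))
    eeg = fg.simulate_eeg(events, kernels, fg.NoiseModel(amplitude_sd=0.0),
                          ["VE"], RATE)
    onsets = [1000.0 + tid * 8000.0 for tid in range(6)]
    epochs, _ = fg.epoch_and_baseline(eeg, onsets,
                                      metadata=pd.DataFrame({"trial_id": range(6)}))
    with pytest.warns(IdentifiabilityWarning):
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            fg.glm_estimate(epochs, events,
                            windows={"s": (-200.0, 800.0), "fp1": (0.0, 600.0)})


# ---------------------------------------------------------------------------
# averaging bias
# ---------------------------------------------------------------------------

def test_bias_zero_without_overlapping_events(small_simulation):
    events = fg.EventStream(small_simulation["events"].stimuli())
    kernels = small_simulation["kernels"]
    times = small_simulation["epochs"].times_ms
    bias = fg.averaging_bias(kernels, events, times, RATE)
    np.testing.assert_allclose(bias.data, 0.0, atol=1e-12)


def test_bias_single_deterministic_shift(kernels):
    rows = [
        (0, "stimulus", 1000.0, 2000.0, np.nan, "", np.nan, np.nan, np.nan, np.nan),
        (0, "fixation", 1250.0, 300.0, 1, "", np.nan, np.nan, 0.0, 0.0),
    ]
    events = fg.EventStream(pd.DataFrame(rows, columns=fg.containers.EVENT_COLUMNS))
    times = np.arange(-100, 1001) * 2.0
    bias = fg.averaging_bias(kernels, events, times, RATE)
    expected = np.zeros_like(times, dtype=float)
    start = np.flatnonzero(np.isclose(times, 250.0))[0]
    n = min(len(kernels.fp1.data), len(times) - start)
    expected[start:start + n] = kernels.fp1.data[:n]
    np.testing.assert_allclose(bias.data, expected, atol=1e-12)


def test_empirical_average_matches_predicted_bias(small_simulation):
    # E[s_avg] = s + bias, checked exactly in the noiseless case
    epochs = small_simulation["epochs"]
    events = small_simulation["events"]
    kernels = small_simulation["kernels"]
    bias = fg.averaging_bias(kernels, events, epochs.times_ms, RATE,
                             trial_ids=epochs.metadata["trial_id"].tolist(),
                             baseline_ms=(-200.0, 0.0))
    from fixglm.validation import _embed
    s_true = _embed(kernels.s, epochs.times_ms, RATE, (-200.0, 0.0))
    s_avg = fg.average_erp(epochs).data[:, 0]
    np.testing.assert_allclose(s_avg, s_true + bias.data, atol=1e-9)
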