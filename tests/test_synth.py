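"""Synthetic generator: catalog composition, scanpath statistics, gaze
rendering and the EEG superposition model."""

import numpy as np
import pandas as pd
import pytest

import fixglm as fg
from fixglm.synth import ScanpathParams, DEFAULT_LANDING_RANK1


# ---------------------------------------------------------------------------
# stimulus catalog
# ---------------------------------------------------------------------------

def test_default_catalog_composition():
    cat = fg.make_stimulus_catalog(seed=0)
    assert len(cat) == 118
    assert cat.n_targets == 70
    assert cat.counts()["neutral"] == 24
    assert cat.counts()["distractor"] == 48


def test_catalog_empty_and_custom_counts():
    assert len(fg.make_stimulus_catalog({c: 0 for c in fg.CATEGORIES}, seed=1)) == 0
    cat = fg.make_stimulus_catalog({"neutral": 3, "disgust": 2}, seed=1)
    # brute-force tally over entries
    tally = {}
    for _, row in cat.entries.iterrows():
        tally[row["category"]] = tally.get(row["category"], 0) + 1
    assert tally == {"neutral": 3, "disgust": 2}


def test_catalog_negative_count_rejected():
    with pytest.raises(ValueError):
        fg.make_stimulus_catalog({"neutral": -1}, seed=0)


def test_catalog_conservation_property():
    for comp in ({"happiness": 5}, {"neutral": 2, "fear": 7, "distractor": 1}):
        cat = fg.make_stimulus_catalog(comp, seed=3)
        assert sum(cat.counts().values()) == len(cat)


# ---------------------------------------------------------------------------
# scanpath
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def calib_events():
    cat = fg.make_stimulus_catalog({"neutral": 500}, seed=21)
    sched = fg.make_trial_schedule(cat, seed=21)
    return sched, fg.simulate_scanpath(sched, seed=21)


def test_scanpath_mean_fixation_count(calib_events):
    sched, events = calib_events
    counts = (events.fixations().groupby("trial_id").size()
              .reindex(sched.trials["trial_id"], fill_value=0))
    sem = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 4.74) <= 3 * sem


def test_scanpath_duration_and_latency_calibration(calib_events):
    sched, events = calib_events
    fix = events.fixations()
    dur = fix["duration_ms"]
    assert abs(dur.mean() - 300.0) <= 3 * dur.std(ddof=1) / np.sqrt(len(dur))
    onsets = sched.trials.set_index("trial_id")["stimulus_onset_ms"]
    first = fix[fix["rank"] == 1]
    lat = first["onset_ms"].to_numpy() - onsets.reindex(first["trial_id"]).to_numpy()
    assert abs(lat.mean() - 250.0) <= 3 * lat.std(ddof=1) / np.sqrt(len(lat))


def test_scanpath_alternation_and_rank_structure(calib_events):
    _, events = calib_events
    for _, grp in events.frame.groupby("trial_id"):
        seq = grp.sort_values("onset_ms")
        seq = seq[seq["event_type"] != "stimulus"]
        kinds = seq["event_type"].tolist()
        # strict alternation, and every rank>=2 fixation preceded by a saccade
        for a, b in zip(kinds, kinds[1:]):
            assert a != b
        ends = (seq["onset_ms"] + seq["duration_ms"]).to_numpy()[:-1]
        starts = seq["onset_ms"].to_numpy()[1:]
        assert np.all(starts >= ends - 1e-6)


def test_scanpath_zero_duration_window():
    trials = pd.DataFrame([{
        "trial_id": 0, "stimulus_id": "x", "cross_duration_ms": 800.0,
        "stimulus_duration_ms": 0.0, "inter_trial_gap_ms": 4000.0,
        "stimulus_onset_ms": 800.0, "condition": "neutral"}])
    sched = fg.TrialSchedule(trials)
    events = fg.simulate_scanpath(sched, seed=0)
    assert len(events.fixations()) == 0
    assert len(events.saccades()) == 0


def test_scanpath_degenerate_landing_all_mouth():
    cat = fg.make_stimulus_catalog({"neutral": 30}, seed=5)
    sched = fg.make_trial_schedule(cat, seed=5)
    params = ScanpathParams(landing_by_rank=({"mouth": 1.0}, {"mouth": 1.0}))
    events = fg.simulate_scanpath(sched, params=params, seed=5)
    r1 = events.fixations().query("rank == 1")
    assert len(r1) and (r1["roi"] == "mouth").all()


def test_scanpath_bad_probabilities_rejected(calib_events):
    sched, _ = calib_events
    params = ScanpathParams(landing_by_rank=({"mouth": 0.6, "eyes": 0.5},))
    with pytest.raises(ValueError, match="sum to 1"):
        fg.simulate_scanpath(sched, params=params, seed=0)


def test_scanpath_reproducible(calib_events):
    sched, events = calib_events
    again = fg.simulate_scanpath(sched, seed=21)
    pd.testing.assert_frame_equal(events.frame, again.frame)


# ---------------------------------------------------------------------------
# gaze rendering
# ---------------------------------------------------------------------------

def test_render_single_fixation_constant():
    from conftest import make_ballistic_events
    ev = make_ballistic_events(n_saccades=0)
    gaze = fg.render_gaze_samples(ev, rate=1000.0, jitter_sd=0.0)
    assert np.ptp(gaze.x_deg) == 0.0 and np.ptp(gaze.y_deg) == 0.0


def test_render_matches_event_trajectory():
    from conftest import make_ballistic_events
    ev = make_ballistic_events(n_saccades=2, amplitude=4.0)
    gaze = fg.render_gaze_samples(ev, rate=1000.0, jitter_sd=0.0)
    # during each fixation the rendered position equals the event position
    for _, f in ev.fixations().iterrows():
        sel = (gaze.time_ms >= f["onset_ms"]) & \
              (gaze.time_ms <= f["onset_ms"] + f["duration_ms"])
        assert np.allclose(gaze.x_deg[sel], f["x_deg"], atol=1e-12)


def test_render_bad_rate():
    from conftest import make_ballistic_events
    with pytest.raises(ValueError):
        fg.render_gaze_samples(make_ballistic_events(), rate=0.0)


# ---------------------------------------------------------------------------
# kernels and EEG synthesis
# ---------------------------------------------------------------------------

def test_default_kernel_extrema_inside_component_windows(kernels):
    s = kernels.s
    w = (s.lags_ms >= 90) & (s.lags_ms <= 130)
    inner = s.data[w]
    # a local signed peak exists inside the P1 window
    assert inner.max() > 0
    peak_lag = s.lags_ms[w][np.argmax(inner)]
    assert 90 < peak_lag < 130
    # earliest positive peak of the first-fixation kernel inside 20-110 ms
    fp1 = kernels.fp1
    d = fp1.data
    peaks = [i for i in range(1, len(d) - 1)
             if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] > 0]
    assert peaks and 20 <= fp1.lags_ms[peaks[0]] <= 110


def test_kernels_no_effect_spec_empty_modulations():
    k = fg.make_default_kernels(500.0, effect_spec=())
    assert k.modulations == ()


def test_simulate_eeg_single_stimulus_identity(kernels):
    frame = pd.DataFrame(
        [(0, "stimulus", 1000.0, 2000.0, np.nan, "", np.nan, np.nan, np.nan, np.nan)],
        columns=fg.containers.EVENT_COLUMNS)
    ev = fg.EventStream(frame)
    eeg = fg.simulate_eeg(ev, kernels, fg.NoiseModel(amplitude_sd=0.0),
                          ["a"], 500.0, duration_ms=4000.0)
    sig = eeg.data[:, 0]
    start = 500  # 1000 ms at 500 Hz, kernel lag axis starts at 0
    np.testing.assert_allclose(sig[start:start + len(kernels.s.data)],
                               kernels.s.data, atol=1e-12)
    assert np.all(sig[:start] == 0.0)


def test_simulate_eeg_two_events_superpose(kernels):
    rows = [
        (0, "stimulus", 1000.0, 2000.0, np.nan, "", np.nan, np.nan, np.nan, np.nan),
        (0, "fixation", 1250.0, 300.0, 1, "eyes", np.nan, np.nan, 0.0, 0.0),
    ]
    frame = pd.DataFrame(rows, columns=fg.containers.EVENT_COLUMNS)
    both = fg.simulate_eeg(fg.EventStream(frame), kernels,
                           fg.NoiseModel(amplitude_sd=0.0), ["a"], 500.0,
                           duration_ms=4000.0)
    # independent summation oracle: render each event alone and add
    parts = []
    for r in rows:
        one = fg.EventStream(pd.DataFrame([r], columns=fg.containers.EVENT_COLUMNS))
        parts.append(fg.simulate_eeg(one, kernels, fg.NoiseModel(amplitude_sd=0.0),
                                     ["a"], 500.0, duration_ms=4000.0).data)
    np.testing.assert_allclose(both.data, parts[0] + parts[1], atol=1e-12)


def test_simulate_eeg_linear_in_kernels(kernels, small_simulation):
    events = small_simulation["events"]
    doubled = kernels.map_kernels(lambda w: w.scaled(2.0))
    a = fg.simulate_eeg(events, kernels, fg.NoiseModel(amplitude_sd=0.0),
                        ["a"], 500.0)
    b = fg.simulate_eeg(events, doubled, fg.NoiseModel(amplitude_sd=0.0),
                        ["a"], 500.0)
    np.testing.assert_allclose(b.data, 2.0 * a.data, atol=1e-12)


def test_simulate_eeg_modulation_shifts_window_mean(kernels):
    mod = fg.Modulation("happiness", "left_frontal", (400.0, 600.0), 1.5)
    k2 = fg.KernelSet(kernels.s, kernels.fp1, kernels.fp2plus, kernels.sp, (mod,))
    frame = pd.DataFrame(
        [(0, "stimulus", 1000.0, 2000.0, np.nan, "", np.nan, np.nan, np.nan, np.nan)],
        columns=fg.containers.EVENT_COLUMNS)
    ev = fg.EventStream(frame)
    base = fg.simulate_eeg(ev, kernels, fg.NoiseModel(amplitude_sd=0.0),
                           ["left_frontal"], 500.0, duration_ms=4000.0,
                           condition_by_trial={0: "happiness"})
    modded = fg.simulate_eeg(ev, k2, fg.NoiseModel(amplitude_sd=0.0),
                             ["left_frontal"], 500.0, duration_ms=4000.0,
                             condition_by_trial={0: "happiness"})
    t = np.arange(base.n_samples) * 2.0 - 1000.0  # ms relative to stimulus
    win = (t >= 400) & (t <= 600)
    delta = modded.data[win, 0].mean() - base.data[win, 0].mean()
    assert delta == pytest.approx(1.5, abs=1e-9)
    # other-condition trials are untouched
    neutral = fg.simulate_eeg(ev, k2, fg.NoiseModel(amplitude_sd=0.0),
                              ["left_frontal"], 500.0, duration_ms=4000.0,
                              condition_by_trial={0: "neutral"})
    np.testing.assert_allclose(neutral.data, base.data, atol=1e-12)


def test_simulate_eeg_rate_mismatch(kernels, small_simulation):
    with pytest.raises(ValueError, match="rate"):
        fg.simulate_eeg(small_simulation["events"], kernels,
                        fg.NoiseModel(amplitude_sd=0.0), ["a"], 250.0)


def test_simulate_eeg_reproducible(kernels, small_simulation):
    ev = small_simulation["events"]
    nm = fg.NoiseModel(1.0, 5.0, seed=77)
    a = fg.simulate_eeg(ev, kernels, nm, ["a", "b"], 500.0)
    b = fg.simulate_eeg(ev, kernels, nm, ["a", "b"], 500.0)
    assert np.array_equal(a.data, b.data)
    c = fg.simulate_eeg(ev, kernels, fg.NoiseModel(1.0, 5.0, seed=78),
                        ["a", "b"], 500.0)
    assert not np.array_equal(a.data, c.data)
    # channels get independent draws
    assert not np.array_equal(a.data[:, 0], a.data[:, 1])
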