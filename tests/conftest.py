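import numpy as np
import pandas as pd
import pytest

import fixglm as fg

RATE = 500.0


@pytest.fixture(scope="session")
def kernels():
    return fg.make_default_kernels(RATE)


@pytest.fixture(scope="session")
def small_simulation(kernels):
    """Eight neutral trials: schedule, scanpath events, noiseless EEG and
    baseline-corrected epochs on one channel."""
    cat = fg.make_stimulus_catalog({"neutral": 8}, seed=11)
    sched = fg.make_trial_schedule(cat, seed=11)
    events = fg.simulate_scanpath(sched, seed=11)
    eeg = fg.simulate_eeg(events, kernels, fg.NoiseModel(amplitude_sd=0.0),
                          ["VE"], RATE)
    meta = sched.trials[["trial_id", "condition"]].copy()
    meta["n_fixations"] = events.n_fixations().to_numpy()
    epochs, skipped = fg.epoch_and_baseline(
        eeg, sched.trials["stimulus_onset_ms"], metadata=meta)
    assert not skipped
    return {"catalog": cat, "schedule": sched, "events": events,
            "eeg": eeg, "epochs": epochs, "kernels": kernels, "rate": RATE}


def make_ballistic_events(n_saccades=3, amplitude=5.0, fix_ms=250.0,
                          sacc_ms=32.0, start_ms=0.0):
    """Hand-built alternating fixation/saccade stream with known geometry."""
    rows = []
    t = start_ms
    x = 0.0
    rows.append((0, "fixation", t, fix_ms, 1, "", np.nan, np.nan, x, 0.0))
    t += fix_ms
    for k in range(n_saccades):
        rows.append((0, "saccade", t, sacc_ms, np.nan, "", amplitude, 0.0, x, 0.0))
        t += sacc_ms
        x += amplitude
        rows.append((0, "fixation", t, fix_ms, k + 2, "", np.nan, np.nan, x, 0.0))
        t += fix_ms
    frame = pd.DataFrame(rows, columns=fg.containers.EVENT_COLUMNS)
    return fg.EventStream(frame)
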