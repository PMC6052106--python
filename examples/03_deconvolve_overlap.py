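"""Average vs GLM deconvolution on overlapping evoked responses.

Simulates epochs whose EEG superposes a known stimulus kernel s(t) with
first-fixation, later-fixation and saccade kernels, then estimates s(t)
two ways: the classical average (biased by overlap) and ordinary least
squares on a stick-function design matrix (which separates the responses).
"""

import numpy as np

import fixglm as fg

rate = 500.0
kernels = fg.make_default_kernels(rate)
catalog = fg.make_stimulus_catalog({"neutral": 40}, seed=3)
schedule = fg.make_trial_schedule(catalog, seed=3)
events = fg.simulate_scanpath(schedule, seed=3)
eeg = fg.simulate_eeg(events, kernels, fg.NoiseModel(amplitude_sd=2.0, seed=3),
                      ["VE"], rate)
epochs, _ = fg.epoch_and_baseline(eeg, schedule.trials["stimulus_onset_ms"],
                                  metadata=schedule.trials[["trial_id"]])

s_avg = fg.average_erp(epochs)
est = fg.glm_estimate(epochs, events)
s_glm = est.estimates["s"]

true = kernels.s


def window_mean(wf, lo, hi):
    lags = wf.lags_ms
    sel = (lags >= lo) & (lags <= hi)
    return float(np.atleast_2d(wf.data.T).T[sel, 0].mean())


print(f"{epochs.n_epochs} epochs, design rank "
      f"{est.diagnostics['rank']}/{est.diagnostics['n_columns']}, "
      f"condition number {est.diagnostics['condition_number']:.0f}")
print("LPP-window (400-600 ms) mean amplitude of the stimulus response:")
print(f"  true kernel : {window_mean(true, 400, 600):7.2f} uV")
print(f"  average ERP : {window_mean(s_avg, 400, 600):7.2f} uV  (overlap-biased)")
print(f"  GLM estimate: {window_mean(s_glm, 400, 600):7.2f} uV  (deconvolved)")

bias = fg.averaging_bias(kernels, events, epochs.times_ms, rate,
                         trial_ids=epochs.metadata["trial_id"].tolist(),
                         baseline_ms=(-200.0, 0.0))
print(f"predicted overlap bias in that window: "
      f"{window_mean(bias, 400, 600):7.2f} uV")
print("-> the averaged ERP inherits the fixation-locked activity landing in")
print("   its late window; the GLM strips it and recovers the true kernel.")
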