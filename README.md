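# fixglm

Overlap-corrected estimation of event-related potentials (ERPs) and
eye-fixation-related potentials (EFRPs) for co-registered EEG /
eye-tracking experiments, with a synthetic data generator that makes the
whole analysis chain testable end to end without any external recording.

## The problem

When observers freely explore a stimulus shown for a long time (here: 2-s
natural emotional faces), every fixation and saccade evokes its own
potential. The classical average of stimulus-locked epochs,

$$\hat s_{Avg}(t) = \frac{1}{E}\sum_{i=1}^{E} x_i(t),$$

is then a biased estimate of the stimulus response: fixation- and
saccade-locked activity superposes on it. The package models each epoch as

$$x_i(t) = s(t) + fp^{(1)}(t-\tau_i^{(1)}) + \sum_{l=2}^{L(i)} fp^{(2+)}(t-\tau_i^{(l)}) + \sum_{l'=1}^{L'(i)} sp(t-\tau_i'^{(l')}) + n_i(t)$$

where $s$ is the response to image onset, $fp^{(1)}$ the first-fixation
response, $fp^{(2+)}$ the response to later fixations, $sp$ the saccadic
potential, $\tau$ the event timestamps and $n_i$ ongoing activity. All
four kernels are estimated jointly by ordinary least squares on a sparse
stick-function design matrix built from concatenated epochs (GLM
deconvolution). The difference between $\hat s_{Avg}$ and the deconvolved
$\hat s_{GLM}$ is the overlap bias, which the package can also predict in
closed form from the event latencies.

Around this core the package provides the full experimental pipeline:
saccade/fixation detection from gaze samples (velocity 30 °/s,
acceleration 8000 °/s², minimum displacement 0.1°), facial
region-of-interest assignment, EEG preprocessing (1–70 Hz band-pass, 50 Hz
notch, average reference, −200..2000 ms epochs, baseline −200..0 ms,
variance- and fixation-count-based rejection, seven virtual electrodes),
component amplitudes (P1 90–130, N170 140–180, P2–P3 200–350, LPP 400–600,
lambda 20–110, P2 180–400 ms), Wagner's unbiased hit rate
$H_u = n_{kk}^2 / (\text{row}_k \cdot \text{col}_k)$, repeated-measures
ANOVA with Greenhouse–Geisser correction and Tukey post hoc tests, and a
Monte Carlo engine mapping detection probability over a
participants × trials grid.

It is intended for researchers analysing free-viewing EEG/eye-tracking
co-registration and for methodologists studying overlap correction.

## Worked example

`examples/03_deconvolve_overlap.py` simulates 40 epochs from known kernels
with free-viewing scanpaths and noise, then estimates the stimulus
response both ways:

```
40 epochs, design rank 1379/1379, condition number 34
LPP-window (400-600 ms) mean amplitude of the stimulus response:
  true kernel :    2.18 uV
  average ERP :    3.90 uV  (overlap-biased)
  GLM estimate:    2.64 uV  (deconvolved)
predicted overlap bias in that window:    1.88 uV
```

The averaged ERP overshoots the true late-window amplitude by ~1.7 µV —
almost exactly the predicted overlap bias — because first fixations
(~250 ms) and second fixations (~500 ms) deposit their own responses
inside the LPP window. The GLM estimate removes them. The other examples
cover simulation (`01`), eye-event detection and ROI assignment (`02`),
the statistical battery (`04`) and the power surface (`05`); each prints
the numbers it computes and a line on what they mean.

A thin CLI wraps the same pipeline: `fixglm --seed 1 demo` runs
simulate → detect → preprocess → estimate → stats → power and writes all
artifacts plus a JSON manifest (exit codes: 0 ok, 2 config, 3 data,
4 numerical).

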