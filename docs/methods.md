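# Methods

This note documents the models, conventions and numerical choices behind
`fixglm`, and what the synthetic validation does and does not establish.

## Superposition model and estimators

Each stimulus-locked epoch is modelled as the sum of four event-locked
kernels plus noise: the image-onset response `s(t)`, the first-fixation
response `fp1(t)`, the rank-2+ fixation response `fp2plus(t)` and the
saccadic potential `sp(t)`, each shifted to its event's timestamp. Kernels
for fixations are split by rank because the first fixation after image
onset carries most of the fast recognition process and differs
oculomotorically from later ones; saccade onsets are modelled so that the
peri-saccadic activity does not contaminate the fixation kernels.

Two estimators of `s(t)` are provided:

* **Averaging** (`average_erp`): the per-lag mean over epochs. Its
  expectation is `s + bias`, where `averaging_bias` computes the bias in
  closed form as the mean over epochs of all non-stimulus kernels shifted
  to their latencies and cropped to the epoch window.
* **GLM deconvolution** (`glm_estimate`): ordinary least squares on a
  sparse 0/1 stick-function design. Rows index concatenated epoch samples;
  each event of class `c` at epoch sample `t0` sets a 1 at row `t0 + l`
  and column `(c, l)` for every lag `l` of that class's estimation window;
  lags falling outside the epoch are dropped. Estimation runs per
  participant × condition on concatenated epochs; a pooled-conditions call
  is simply a single fit over all epochs.

Default estimation windows: `s` ∈ [−200, 800] ms (stimulus-evoked activity
fades after roughly 700 ms), `fp1` and `fp2plus` ∈ [−200, 600] ms, `sp` ∈
[−50, 100] ms; all configurable. Saccades enter as stick onsets only;
amplitude/orientation covariate expansions are out of scope.

### Numerics

The solver forms the normal equations once per fit (`X` is sparse; `XᵀX`
is a few-thousand-square dense matrix) and uses a Cholesky factorisation,
shared across channels. If the factorisation detects near-singularity
(relative pivot below 1e-7) it falls back to an SVD least-squares solve of
the normal system, whose minimum-norm solution coincides with the
pseudo-inverse solution of the original problem; a
`RankDeficientDesignWarning` is emitted. The design condition number
(square root of the `XᵀX` eigenvalue ratio) is reported in the
diagnostics; its computation can be switched off for speed. An
`IdentifiabilityWarning` fires when first-fixation latencies have an SD
below 2 samples, since the `s` and `fp1` column blocks then become nearly
collinear. Ridge regularisation is available (`ridge > 0`) as a clearly
non-default extension; the default is pure OLS.

Event timestamps are converted to samples by rounding each absolute time
independently (round-half-to-even), exactly as epochs are cut, so that a
noiseless simulation is reproduced to machine precision. Baseline
correction precedes estimation.

## Synthetic data generator

The generator emulates a free-viewing experiment on static emotional
faces: 118 stimuli (24 neutral, 12 happiness, 12 surprise, 10 fear,
12 disgust, 48 distractors), trials consisting of a fixation cross
(uniform 700–1200 ms), a 2-s stimulus and a 4-s grey gap.

**Scanpaths.** Within the stimulus window events alternate
saccade → fixation → … (the opening saccade leaves the cross). The model:

* first-fixation latency ~ Normal(250, 35) ms, floored at 80 ms;
* fixation durations log-normal; the first fixation is drawn shorter
  (mean 212, SD 70 ms) than later ones (mean 365, SD 110 ms) so the
  rank-2 onset lands near 500 ms while the whole-trial mean duration sits
  near 300 ms;
* after each fixation exploration terminates with probability 0.055
  (geometric stopping). The emulated behavioral statistics — ~4.74
  fixations per trial, ~300 ms mean duration, first fixation ~250 ms —
  cannot all hold under uninterrupted back-to-back chaining inside 2 s,
  so early termination is a structural part of the model (empirically,
  observers pause or blink); after the last fixation no further events
  are emitted;
* landing regions drawn per rank from the observed first/second-fixation
  ROI distributions (eyes and nose dominate); positions uniform within
  the region's pixels; landings closer than 1° to the current position are
  resampled because such micro-refixations are below the detector's
  resolution and are not modelled;
* saccade durations follow a main-sequence rule, 21 + 2.2·amplitude ms.

The fixation ongoing on the cross at stimulus onset is not an event;
rank 1 is the first fixation after image onset.

**ROI layouts** are geometric rectangles/ellipses (forehead, brows,
corrugator, eyes, nose, mouth, chin on a 30 × 40° face; background
`out`) — synthetic stand-ins for hand-segmented masks, sufficient for
positional statistics but without photometric content.

**EEG synthesis** is the superposition model itself at 500 Hz by default
(half the hardware rate of the emulated acquisition, halving design
size; configurable). Default kernels are Gaussian-bump morphologies whose
extrema fall inside the standard component windows (P1/N170/P2–P3/LPP for
`s`; lambda and P2 for the fixation kernels). Condition effects are
additive offsets on a (condition, site, window) triple, applied to `s` by
default and optionally to fixation kernels. Noise is 1/f^α Gaussian
(α = 1), independent per channel, scaled to a requested RMS. One master
seed derives per-trial and per-channel substreams, so all outputs are
bit-reproducible.

What the generator does **not** emulate: blinks and ocular artifacts
(recordings are artifact-free, so the artifact-correction hook is a
pass-through), photorealistic faces, luminance effects on the lambda
response, pupil data, drift or calibration error beyond white positional
jitter, and spatially correlated noise across channels. Passing tests
therefore demonstrate the correctness of the estimation machinery under
the stated model, not robustness to real-world artifacts.

## Eye-event detection

Velocity and acceleration are central differences of the gaze trace,
each smoothed with a 5-sample moving average (the hardware parser is
proprietary; this is documented and configurable). A candidate saccade is
a run of samples with speed above 30 °/s; runs separated by less than the
40 ms minimum fixation duration are merged; a run qualifies as a saccade
if its peak acceleration exceeds 8000 °/s² and its displacement exceeds
0.1° (the published "0.1 °/s" motion minimum is read as a displacement —
standard parser semantics; the unit is taken to be a typo). Intervals
between saccades are fixations summarised by their centroid (the source
protocol does not state centroid vs first sample; centroid chosen).
Fixation positions map to ROI labels by nearest-pixel lookup;
off-raster positions are `out`. Forehead and chin are assigned but
excluded from rank statistics by default (they attract well under 1% of
fixations).

## Preprocessing conventions

Band-pass 1–70 Hz and 50 Hz notch filtering are zero-phase FIR filters
(via MNE). Average re-referencing subtracts the per-sample channel mean.
Epochs span −200..2000 ms inclusive at both ends (1101 samples at
500 Hz); timestamps convert to samples by round-half-to-even. Baseline is
the −200..0 ms mean per epoch and channel; the correction is idempotent.

Epoch rejection is single-pass: an epoch is rejected when its variance
(time-variance per channel, reduced over channels by the unweighted mean;
`max` reduction available) exceeds the across-epoch mean plus 3 SD, or
when fewer than two fixations occurred in the trial. Variance is computed
on the full channel set before virtual-electrode pooling (the alternative
order is not exposed). Participants are excluded unless every condition
retains at least five epochs. The seven virtual electrodes are unweighted
means of fixed 10–20 channel groups (left/right frontal, left/right
centro-parietal, left/right parieto-occipital, median occipital).

## Component statistics

Component amplitude is the unweighted mean over an inclusive latency
window. EFRP windows default to lambda [20, 110] and P2 [180, 400] ms —
the bounds the reported tests are labelled with; the narrower
[20, 100]/[180, 300] preset is provided because both appear in the source
material, and the discrepancy is unresolved there.

The repeated-measures ANOVA uses the orthonormal-contrast decomposition:
for each effect, subject × cell means are projected onto orthonormal
contrasts (Kronecker products of Helmert contrasts and normalised
averaging vectors), giving the univariate F with df (q, q(n−1)),
Greenhouse–Geisser ε = (tr S)²/(q·tr S²) clipped to [1/q, 1], and
Mauchly's W with Box's chi-square approximation including the
second-order correction term. The GG-adjusted p is reported always and
substituted as `p_corrected` when Mauchly's test is significant. One and
two within factors are supported; the implementation is cross-checked in
the test suite against pingouin (one-way, sphericity) and statsmodels
AnovaRM (two-way F). Tukey HSD uses the condition × subject interaction
mean square as error with (k−1)(n−1) df (the conventional within-subject
error term) and studentized-range p-values. One-sample t-tests report
partial η² = t²/(t²+df); zero variance with nonzero mean yields an
infinite t with a warning.

Wagner's unbiased hit rate is `n_kk² / (row_k · col_k)`, defined as 0
when either marginal is empty. Post hoc re-categorization relabels each
trial with the participant's own category response and drops the
badly-recognised category (fear) entirely.

## Monte Carlo validity engine

The published simulation protocol is not printed in the available
material, so the engine adopts a two-level Gaussian hierarchy and exposes
every SD: participant i's mean in condition c is
`b_i + δ·[c = 2] + e_ic` with `b_i ~ N(0, between²)` and
`e_ic ~ N(0, within²/trials)`. The default detection test is the paired
contrast at α = .05 (the LPP-style two-condition comparison); any callable
`(y1, y2, alpha) → bool` can be substituted. `power_surface` maps the
detection fraction over a participants × trials grid, reproducibly from
one seed. A full-pipeline mode (resimulating EEG and re-running the
estimators inside each replicate) is achievable by composing the public
API as in `tests/test_acceptance.py`'s recovery experiment, but the
amplitude-level engine is the default because it is what the validity
question — how test outcomes scale with N and trials — requires.

## Validation experiments and problem sizes

`fixglm.validation` holds the canonical experiments:

* `kernel_recovery_experiment`: 19 simulated participants × 13 trials ×
  4 conditions (988 epochs) at 500 Hz over the seven virtual electrodes,
  noise at SNR 1 (noise RMS equal to noiseless signal RMS within epochs).
  Kernels are estimated per participant × condition and grand-averaged
  over fits and channels; recovery is scored as RMSE normalised by the
  true kernel's RMS. The averaging bias check correlates the grand
  average's deviation from the true `s` with the closed-form prediction.
* `no_overlap_equivalence`: one stimulus event per epoch; the GLM and the
  average must agree to numerical precision.
* `scanpath_calibration`: 600 trials; reports mean fixations/trial,
  first-fixation latency and fixation duration with standard errors.

These sizes run the whole validation suite in well under a minute on one
core while leaving the Monte Carlo standard errors small relative to the
tolerances tested.

## Known limitations

* The generator's scanpath model is parametric (log-normal durations,
  geometric stopping, rank-wise landing probabilities); it reproduces
  first-order behavioral statistics, not sequential dependencies such as
  inhibition of return or saccade-amplitude/duration coupling with
  content.
* OLS assumes noise whiteness it does not have under 1/f activity; the
  estimator stays unbiased but not minimum-variance. No GLS/whitening is
  provided.
* Rank-deficient designs return the minimum-norm solution, which splits
  shared responses across collinear kernel blocks rather than attributing
  them.
* The detector is offline and monocular; no blink handling or pupil
  processing.
* BIDS export, bad-channel interpolation and ocular-artifact correction
  are out of scope; the artifact hook is a pass-through.
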