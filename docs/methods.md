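# Methods

## Problem and approach

Children at high risk of dyslexia (HR) move their eyes differently from
low-risk readers (LR) while reading a multi-line text: they read more
slowly, fixate longer, and make more regressions (right-to-left
re-reading movements). The gaze x-coordinate over time is a saw-tooth:
one near-linear left-to-right sweep per text line followed by a return
sweep, so an ideal trace has as many teeth as the text has lines.

`dyslexiscan` classifies the *entire* pre-processed x-trace rather than
hand-engineered fixation/saccade features. The pipeline is:

1. average the left- and right-eye x-traces, discard the y-traces;
2. trim to the active reading part (a per-recording annotation — gaze
   wandering after the last line is not part of the reading signal);
3. bring all traces to a common length `N` (the slowest reader's
   length), by either **zero padding** or **cosine-basis
   interpolation**;
4. optionally take the **magnitude spectrum** (|DFT|, DC excluded,
   first half retained — bins `1..⌊N/2⌋`);
5. classify with a small 1D CNN; aggregate over a constrained
   many-fold cross-validation.

The four branch combinations probe what information the classifier
uses: zero padding keeps reading time implicitly (the number of padded
zeros); interpolation removes it and keeps only waveform shape; the
magnitude spectrum additionally removes the *positions* of regression
events (position is phase information), which is useful because
regressions occur at random lines.

## Cosine-domain resampling

The interpolation uses the orthonormal DCT-III synthesis basis

    U[k, n] = sqrt(2/N) · c_n · cos(π (2k+1) n / (2N)),
    c_0 = 1/√2,  c_n = 1 (n ≥ 1),

with `k` the sample index and `n` the harmonic index; the normalisation
`c_n` makes `U` orthogonal, which in turn makes Parseval's identity
hold exactly for the analysis step (tested to 1e-10). A length-`M`
signal is analysed into `M` orthonormal cosine coefficients, the
coefficient vector is zero-extended (or, when shrinking, truncated) to
`N`, synthesised with the length-`N` basis, and rescaled by `√(N/M)` so
that a constant maps to the same constant. This is the canonical
transform-domain resampling: a pure time dilation of the waveform,
exactly the identity at `N = M`.

### The length-ratio ("energy") correction

After interpolation each signal may be multiplied by the length ratio
`r = M/N` (`energy_correction="ratio"`, the default), by `√(M/N)`
(`"sqrt_ratio"`, the factor that exactly preserves energy under an
orthonormal resampler), or left untouched (`"none"`). Note a
consequence of any length-dependent rescaling: it re-introduces reading
time into the nominally time-free interpolated representation as a
per-subject amplitude. The information-removal experiments in the test
suite therefore run with `"none"`, which is the configuration under
which "interpolation removes reading speed" is exactly true; the
default remains `"ratio"` for fidelity to the published pipeline.

### Spectrum conventions

`magnitude_spectrum` keeps bins `1..⌊N/2⌋`: the DC bin only encodes the
horizontal centre of the text on screen, and the upper half of a real
signal's spectrum mirrors the lower half. The Nyquist bin is retained
for even `N`.

## Synthetic cohorts

The study cohort the method was designed around is not distributable,
so the package ships a generator that reproduces the *morphology* the
method relies on, with defaults mirroring the published stimulus: 8
text lines, on average 4.6 words per line, 100 Hz sampling.

Per line, a subject sweeps from `x_start` to `x_end` at constant speed
over a log-normal duration (LR mean 2.2 s, sd 0.55 s — about 18 s per
text, a realistic oral-reading pace for 9–10-year-olds on a ~37-word
text; per-line word counts modulate the mean). HR line durations are
multiplied by `hr_slowdown_factor` (default 1.5). HR traces
additionally contain regressions: Poisson(`regression_rate_per_line`,
default 1.5) events per line, placed uniformly, each an instantaneous
backward jump of 0.3 line widths followed by a forward re-read at
normal speed (so regressions also lengthen HR traces, as in real
reading). Gaussian fixation jitter (sd 4 screen units) and independent
per-eye noise (sd 1.5) are added on a 100–900 coordinate range.
Line returns are single-sample resets: at 100 Hz a return saccade
spans ≲1 sample and carries no class signal of interest. The y-traces
are a line-index staircase, present only so the data model is complete
(they are dropped before representation building).

Per-subject random streams are derived from `(seed, subject_index)`, so
cohorts are bit-reproducible and independent of generation order.

Two control configurations isolate specific information channels:

* **time-matched** (`hr_slowdown_factor=1, hr_time_compensation=True`):
  HR line durations are shrunk by the expected re-reading overhead
  `1 + rate·span`, so both groups have equal expected reading time but
  different waveform shape — reading time carries no signal, shape does.
* **speed-only** (`simulate_speed_dilated_cohort`): every subject's
  waveform (noise included) comes from one LR-morphology process at a
  reference length; HR waveforms are then dilated in time with the
  cosine resampler. The classes differ in reading speed and in
  *nothing* else. This construction matters: naively generating
  slowed-down traces with independent per-sample noise leaves a
  noise-bandwidth signature after length normalisation (shorter traces
  are stretched more, hence smoother), which a CNN can exploit; pure
  dilation has no such leak, so chance-level accuracy under the
  time-free representation is guaranteed by construction rather than
  hoped for.

What the generator does **not** emulate: fixation/saccade
micro-dynamics (main-sequence velocities, fixation-duration
distributions), blinks and tracking dropouts, drift and calibration
error, within-line word-frequency effects, and any correlation between
regression frequency and slowdown beyond their joint dependence on the
label. Passing tests on synthetic cohorts therefore show the pipeline
is correct and sensitive to the intended signal (slowdown +
regressions), not that the reported field accuracies transfer to any
particular clinical population.

## Classifiers

Three CNN depths are provided (`cnn2/cnn3/cnn4`): stacks of
`conv(1×3, 'same') → batch norm → ReLU → max pool(1×2, stride 2)` with
8, 16, 32, 64 kernels, then a two-layer fully connected head (hidden
width 64, ReLU) ending in a 2-way softmax. Training minimises
cross-entropy with SGD + momentum (lr 0.01, momentum 0.9, batch 16, up
to 100 epochs, early stopping with patience 15 on validation accuracy,
best-validation checkpoint restored). The networks are implemented
directly in numpy (im2col + GEMM convolutions, explicit
backpropagation), which keeps training fully deterministic under a
seed on a single CPU.

Choices the architecture description leaves open, fixed here:
convolution padding is `'same'` (pooling alone controls downsampling);
batch norm sits between the convolution and the ReLU; momentum 0.9;
FC hidden width 64; batch 16 / 100 epochs / patience 15. All are
configurable.

Inputs are standardised per feature (z-score) with statistics computed
on the training split only and stored on the model
(`TrainConfig.input_norm`, default `"zscore"`; also `"zerocenter"`,
`"none"`). Raw inputs span screen coordinates (~10²) to spectrum
magnitudes (~10⁵), and at the fixed learning rate of 0.01 unnormalised
inputs destabilise SGD; input-layer standardisation is the standard
remedy and every mainstream CNN toolkit applies one by default.

HR is the positive class throughout (a missed at-risk reader is the
costly error), so TPR is sensitivity to dyslexia risk and TNR is
specificity.

The **reading-time baseline** classifies a subject as HR when their
active reading time exceeds a threshold chosen by exhaustive search
over midpoints of adjacent sorted training times (ties resolve to the
smaller threshold). Both a cross-validated and a resubstitution
(single threshold on the whole cohort) variant exist.

## Evaluation protocol

`generate_folds` draws 100 balanced test folds of 16 subjects (8 HR,
8 LR) such that no two folds share more than 50% of their members
(checked over all 4,950 pairs). The sampler is stratified rejection
sampling with a retry budget (10,000 per fold) and a deterministic
greedy repair fallback; an unattainable constraint raises an error and
is never silently relaxed. Remaining subjects are split 90/10 into
training and validation, stratified with largest-remainder rounding.

Per fold, the cohort target length `N` is the longest trimmed signal
among that fold's **non-test** subjects (`target_length_policy=
"per_fold"`), so nothing about the test subjects can influence the
fitted representation; a test signal longer than `N` is resampled down
in the interpolated branches and rejected with an error in the
zero-padding branches. `"global"` mode instead fixes `N` to the
slowest reader of the whole cohort — the published procedure, and the
practical choice for zero-padding branches where the slowest subject
may land in a test fold. Per-fold metrics are aggregated as mean ±
sample standard deviation (ddof = 1) across folds; confusion counts
are never pooled across folds.

The leakage audit is part of the test suite: replacing a test fold's
traces changes neither the fitted target length, nor the threshold,
nor a single network weight at fixed seed.

## Problem sizes in the test suite

The packaged experiments run at desk scale, chosen as the package's
own test conditions: separability of the default cohort uses 60 HR +
60 LR subjects and 20 folds with the 3-layer CNN on the spectrum of
interpolated signals; the information-removal contrast uses the
speed-only cohort (60 + 60, 20 folds) under time-interpolated versus
zero-padded representations; the fold-constraint check runs at the
full 97 + 88 cohort size with 100 folds. Unit tests use shorter line
durations (0.3–0.4 s) purely to keep individual traces small.

## Known limitations

* The CNN runs on a single CPU thread of execution; wall-clock cost
  grows linearly with target length `N`, so very slow readers make
  every subject's representation longer.
* The end-of-reading index is an annotation, not detected; the
  optional tail simulation exists to exercise trimming, not to model
  post-reading gaze realistically.
* Chance-level results on 16-subject folds are coarse (one subject is
  6.25 accuracy points); chance-band assertions use wide bands.
* The generator's defaults are calibrated to qualitative trace
  morphology and relative group orderings, not to any quantitative
  clinical distribution.
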