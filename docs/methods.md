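# Methods

This note documents the models, defaults and design choices behind
`v1facedecode`, and what the synthetic experiments do and do not establish
about real fMRI data.

## Forward model

A run is simulated as

    data = (trial boxcars ⊛ HRF) · A + drift + noise

where `A` is the ground-truth amplitude matrix. Each trial's regressor is a
boxcar of the stimulus duration (1 s = 1 volume at TR = 1 s) convolved with
the HRF kernel and truncated at the run end; the signal is therefore exactly
linear in the amplitudes, which is what makes noiseless GLM recovery an
exact (1e-6) test rather than an approximation.

**Amplitudes.** `PatternTruth` maps (condition, task, voxel) to a response
amplitude. Face conditions drive all V1 voxels at `base_response`
(default 1.0 BOLD unit); the eye/mouth checkerboard mapping conditions drive
their ground-truth patches at `mapping_response` (default 2.0, smoke config
2.5); fixation drives nothing. Class information is injected as zero-mean
Gaussian multivoxel patterns with per-voxel standard deviation
`cnr × sigma`, drawn independently per expression condition. Gender is an
attribute of face trials (balanced within each run × condition cell), not a
separate condition; it contributes an additive per-voxel pattern
(`gender_map`), which is what lets the same trials support both the
expression and the gender classifications, as in the modelled experiment.
Setting both CNRs to zero gives the null construction: amplitudes identical
across the to-be-decoded labels.

**Noise and drift.** White Gaussian noise of standard deviation `sigma`
(default 1.0) per voxel and volume, optionally AR(1)-filtered
(innovation-sd convention; coefficient 0 by default since the modelled
acquisition specifies no noise process), plus a linear drift of
`drift_slope` units/volume (default 0.01). The default per-voxel
contrast-to-noise ratio for class patterns is 0.5. These are stand-in
values: real V1 BOLD has structured spatio-temporal noise, physiological
confounds and spatial smoothness that the generator does not emulate, so
passing tests demonstrate the *estimators'* correctness and calibration,
not expected real-data effect sizes.

**Design.** Six runs alternating expression/gender tasks, 120 trials per
condition total (20 per run), 4 s SOA (1 s stimulus + 3 s fixation gap),
randomly ordered within run. Run length is lead-in (10 volumes) + trial
block + lead-out (10 volumes); onsets sit on the volume grid so
nearest-volume rounding is exact. The approximately-8.5-minute run length of
the modelled experiment is not matched exactly — only the SOA and trial
counts are specified quantities.

**Wedge runs.** The rotating wedge sweeps 360° per 32-volume cycle; a voxel
with preferred angle θ is driven for the 45° (4-volume) window starting at
`round(θ/360 · 32)`. The neural boxcar is *circularly* convolved with the
HRF (kernel aliased onto the cycle), so the response and the analysis
reference are exactly periodic and noiseless phase recovery is exact. The
cycle count defaults to 8 (not specified by the modelled protocol). Region
truth places eye-patch angles in a ventral band around 270° and mouth-patch
angles around 90°, echoing upper/lower-field retinotopy of a fixated face.

**Gaze.** Fixation jitter is white Gaussian position noise (default SD
0.05–0.1°) at 60 Hz — the eyetracker rate is not specified by the modelled
experiment, and 60 Hz makes a 150 ms saccade span 9 samples. Saccades are
injected as square-pulse excursions; no blinks, drift or calibration error
are modelled.

## Estimation choices

**HRF.** Double gamma: peak delay 6 s, undershoot delay 16 s, dispersions
1, peak:undershoot ratio 6, length 32 s, sampled at TR and peak-normalized;
only "a standard two-gamma" is specified by the modelled analysis, so the
constants are exposed in config and no result depends on them — recovery
tests are self-consistent (the same kernel generates and fits). Exactness
tests use a 19 s (20-tap) kernel so the 20-bin FIR window covers the full
response support; with the 32 s default the unmodelled tail biases FIR bins
by ~0.07 amplitude units, which is a property of windowed FIR estimation,
not an implementation error.

**High-pass filter.** Implemented as projection on an orthonormalized drift
basis containing the DCT-II cosines *and their quadrature sine partners* at
every frequency below 0.006 Hz, after mean-removal so the voxel mean is
preserved. A cosine-only basis leaves up to ~18% of an arbitrary-phase
sub-cutoff sinusoid; adding the sine partners makes removal phase-free
(<1% residual) while leaving components at ≥5× the cutoff essentially
untouched (within ~1%). The operator is linear and idempotent; detrending
runs first, filtering second.

**OLS.** Plain voxel-wise least squares (no prewhitening), `dof = n −
rank(X)`; rank-deficient designs fall back to the minimum-norm
pseudo-inverse with a warning. Note that a design with *no* rest gaps and a
fixed SOA is rank-deficient for FIR estimation — the fixation trials in the
default design are what make the deconvolution identifiable.

**Peak selection.** The peak bin within 5–7 s is chosen where the grand
mean *across* the compared conditions is maximal, and condition values are
read at that shared bin; selecting per condition would bias the
classification contrast. The window summary averages bins in 3–9 s
inclusive.

**Fixed effects.** `fixed_effects_design` builds the concatenated-cohort
design (one predictor per condition, one intercept per subject-run). The
pipeline's per-timepoint inference uses group t-tests on FIR betas per bin
with Holm–Bonferroni correction across bins within each task × region
family — an equivalent inferential surface that avoids assembling a single
giant cohort GLM.

## Patch definition

Strict threshold |t| ≥ 3.2 on the eye-minus-mouth contrast (sign
convention: positive = eye); the modelled analysis adjusted this slightly
per subject by eye, which is replaced by the single configurable value.
Dilation uses a lowered threshold (default 1.5 — unspecified in the
modelled analysis, exposed in config); rest-of-V1 = V1 mask − dilated
patches, intersected with the responsive map (faces-minus-baseline,
Bonferroni-corrected p < 1e-4; the correction method is configurable since
only "corrected" is specified). The V1 mask comes from the generator's
region labels, standing in for manual surface-based delineation. Empty
patches warn rather than fail.

## Decoding

Normalization maps each feature affinely so the *training* extrema are
exactly ±1 (constant features map to 0, keeping the transform total); test
data reuse the training min/max/range and may leave [−1, 1]. The classifier
is libsvm's linear SVC with C = 1, one-vs-one voting for the three-class
problem (ties broken by the underlying implementation's class ordering).
Averaged-mode testing averages *raw* test betas per class before applying
the training normalization. Sub-sampling uses 15 evenly spaced sizes from 1
to min(features, 160) — the modelled description's "1:10:160" enumerates 16
values but states 15 sizes; the stated count and maximum win — with 30
draws per size, each draw seeded deterministically from (seed, fold, size,
draw); accuracies average over draws within fold, then over folds. Chance
for the three-way problem is 100/3%. Group inference is a one-tailed
one-sample t-test against chance with dof = n − 1.

## Repeated-measures ANOVA

Each within-subject effect is tested against its own effect-by-subject
interaction (F(1, 8) for two-level factors and nine subjects). Sphericity
corrections are omitted: all factorial analyses here use two-level factors
(plus one three-level region factor in the accuracy ANOVA), and the
package's calibration tests verify the type-I rate empirically. Zero
error-variance cells are reported as F = 0 with a `degenerate` flag.

## Problem sizes

The default configuration is the full study geometry: 9 subjects, six
500-volume runs, 800 voxels (160 eye, 160 mouth, 400 rest, 80 outside).
A complete default cohort runs in well under a minute. Calibration suites
use a scaled "smoke" configuration — 6 subjects, 24 trials per condition,
120 voxels, 2 wedge cycles, no set-size curves — chosen so that
multi-seed calibration (50 independent cohorts) remains an interactive-scale
computation while preserving the six-run alternating-task structure and the
full region × task × classification × test-mode grid.

## Known limitations

- No spatial structure: voxels are exchangeable units; no smoothing,
  searchlights, or surface geometry.
- No motion, spikes, physiological noise, or slice timing; preprocessing
  stages for those are intentionally out of scope.
- The eccentricity dimension of retinotopy and field-sign-based area
  borders are not implemented; region membership is ground truth.
- The null-calibration guarantees are about the *pipeline* (no leakage, no
  optimistic bias); they do not certify power or effect sizes on real data.
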