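# Methods

This note records the modeling choices, defaults and known limitations of
`pdmotion`, in the spirit of a model-description appendix.

## Signal model and preprocessing

Input is tri-axial acceleration in g from up to five body sites
(left/right wrist, left/right ankle, chest), sampled at 51.2 or 62.5 Hz
within ±6 g. The chest device is mounted with its x axis vertical, so x
carries a +1 g gravity component while the wearer is upright; this DC
component encodes orientation, not movement.

All channels pass through a causal order-4 Butterworth low-pass IIR with a
3 Hz cutoff before any parameterization. Rationale: parkinsonian rest
tremor occupies roughly 4–6 Hz while the frequency content of voluntary
everyday movement lies below 3 Hz, so the filter strips the
symptom-induced interference that would otherwise dominate wrist channels.
Measured response at 51.2 Hz: ≈0.0006 dB at 1 Hz, ≈18.5 dB attenuation at
5 Hz. The filter is causal (single-pass) by default because a wearable
monitor runs online; a zero-phase two-pass variant (`zero_phase=True`)
exists for offline analysis. Framing uses rectangular windows (no taper),
`floor` sample counts, and drops a trailing partial window.

Frame labels come from the activity intervals by majority occupancy, with
exact ties going to the earlier-starting interval and uncovered time
counting as background. The gait task collapses activities to
gait/no-gait; the hand task to left/right/both/no-movement.

## Features

Per axis and frame: mean, standard deviation (N−1 denominator), kurtosis,
crest factor, spectrum energy, spectral entropy; per sensor, the three
axis-pair correlations; per sensor pair, the three same-axis correlations.
The spectrum is the one-sided DFT magnitude with the DC line excluded
(K = ⌊N/2⌋ lines) so that the gravity offset cannot dominate energy and
entropy.

Two formulas are implemented in *both* their published and conventional
forms, selected by `FidelityOptions`:

* **Kurtosis.** The published form divides the fourth central moment by
  the *squared* standard deviation (`m4/std**2 − 3`), which is
  dimensionally inconsistent with excess kurtosis but is what the original
  description states; it is the default for fidelity. `kurtosis="standard"`
  gives `m4/std**4 − 3`. Both are oracle-tested. For classification the
  choice is immaterial up to the monotone per-dimension ⟨−1,1⟩
  normalization when frame lengths are fixed.
* **Correlation.** The published estimator mixes a 1/N cross-moment with
  (N−1)-denominator standard deviations, so literal self-correlation is
  (N−1)/N. The default is the consistent Pearson estimator
  (`corr(x,x) = 1`); `correlation="as_printed"` keeps the literal form.

Spectral entropy treats the normalized amplitude spectrum as a probability
mass function (point-mass spectrum → 0 bits; flat spectrum → log₂K bits);
"probability of amplitude occurrence" is ambiguous in the source
description, so a 32-bin amplitude-histogram estimate is available as
`entropy="histogram"`. An all-zero spectrum is defined to have energy 0
and entropy 0.

Degenerate frames (zero variance → kurtosis and correlations undefined;
zero RMS → crest undefined) yield NaN sentinels that vector assembly
replaces with 0, keeping classifier inputs fixed-length; replacement
counts are logged. Features are computed on filtered signal throughout.

Normalization maps each dimension affinely onto [−1, 1] using training-set
min/max only; test values outside the training range clamp to ±1, and a
constant training dimension maps to 0.

## Classifiers

**Neural network.** One hidden layer of ⌈n_in/2 + n_out⌉ neurons (rounded
up for odd inputs — more capacity, deterministic), bipolar sigmoid
activation on both layers, one-hot targets coded in {−1, +1}, full-batch
gradient descent on the mean squared error with learning rate 0.01,
momentum 0.9, 500 epochs, uniform(−0.5, 0.5) seeded initialization.
Training is bit-reproducible for a fixed (data, config, seed). The
published activation β(1−e^{αx})/(1+e^{αx}) is a *decreasing* sigmoid
(equal to −β tanh(αx/2)); the default uses the increasing tanh(αx/2) —
functionally equivalent up to weight signs — with the literal form behind
`activation_mode="as_printed"`.

**SVM.** Soft-margin Gaussian-kernel C-SVC via libSVM (through
scikit-learn), defaults C = 62.5, γ = 0.5. The γ parameter follows the
libSVM/OpenCV convention K(u,v) = exp(−γ‖u−v‖²) — the implementations in
which those values were originally selected; under the alternative
reading exp(−‖u−v‖²/(2γ²)) the same γ collapses the kernel on
135-dimensional normalized inputs and the classifier degenerates to
majority voting. The published kernel formula with an *unsquared*
distance is preserved as `kernel_mode="as_printed"` (a valid kernel — the
exponential/Laplacian family — just not the one the cited libraries
compute). Grid search is exhaustive over C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}
(odd powers of two) with stratified internal folds; ties break toward
smaller C, then smaller γ.

**Hand task.** One-vs-all: one binary machine per class, each
Platt-calibrated; prediction is the argmax of the per-class probabilities
(first class in vocabulary order on exact ties). The cascade feeds the
hand classifier only frames whose time span does not overlap any
gait-labeled gait-task frame.

## Evaluation

*Effectiveness* is per-class recall in percent — the only reading
consistent with separate per-class rows in the original result tables.
*Second-order error* is the share of frames assigned to a class that truly
belong elsewhere (per-predicted-class false-discovery percentage — the
only reading that allows near-100 % effectiveness alongside ~50 % error
for a dominant class). Both interpretations are documented assumptions.
SDs use the N−1 denominator across folds/subjects. Leave-one-subject-out
fits the normalizer and classifier on the n−1 training subjects only;
cross-validation is stratified at frame level with k = 10 by default.

## Synthetic cohort generator

The generator emulates the recording protocol: a scripted sequence of
everyday activities — stand, walk with a turn, object/hand lifts with
left/right/both hands, sit↔stand, lie↔rise, static postures — each
bracketed by static posture and repeated three times per session, with
video-grade interval labels by construction.

Signal structure, per activity:

* gravity: +1 g on chest x while upright, on chest z while lying;
* gait: on each ankle, an antiphase fundamental at the subject's step
  frequency (drawn U[0.8, 1.2] Hz) on the forward (z) axis plus a weak
  second harmonic, and on the vertical (x) axis an *in-phase* component at
  twice the step frequency (both feet strike within one stride) over a
  weaker antiphase term — so inter-ankle correlation rises during gait;
  attenuated copies on chest and wrists (arm swing);
* hand lifts: half-sine enveloped ~1 Hz bursts (default 0.5 g) on the
  named wrist(s), slight chest lean for object lifts;
* transitions: enveloped chest bursts;
* tremor: a 4–6 Hz oscillation on both wrists (default 0.05–0.15 g),
  deliberately above the 3 Hz cutoff so the filter's purpose is testable;
* white Gaussian sensor noise (default σ = 0.05 g), then clipping to ±6 g.

Amplitudes are plausibility choices — no amplitude statistics for patient
movement were available — fixed once at values giving realistic
signal-to-noise for each activity class. One master seed; per-subject
seeds are base_seed + index.

What passing tests show — and don't: the generator produces the
periodicity, inter-limb correlation and band structure the features
assume, so green tests demonstrate that the pipeline's machinery (filter,
framing, features, normalization, cascade, protocols) is correct and that
the classifiers can exploit that structure across subjects. They do *not*
certify clinical accuracy: real PD signals add gait asymmetry and
festination, freezing episodes, dyskinesia, sensor artifacts and label
noise that the sinusoid-plus-noise model does not emulate, and the
reported synthetic effectiveness values are accordingly optimistic.

Default problem sizes for the shipped experiments: 10-subject cohorts,
one repetition of the 70 s activity sequence per session, three cohort
seeds — about 1100 gait frames and 2200 hand frames per cohort.

## Virtual TouchPad

Background model: per-pixel mean and mean absolute successive difference
over the first 50 frames. Foreground: |I − mean| > λ·max(diff, floor)
with λ = 3 and floor = 2 intensity levels (the floor keeps noise-free
pixels from becoming hypersensitive). Shadow removal applies only to
color frames (luma ratio in [0.5, 0.95] with chroma shifts ≤ 12 in
YCrCb — thresholds follow the classical detector family, configurable);
grayscale input skips the stage with a logged notice. Closing uses a 5×5
elliptical (disk) element. The hand is the largest connected component,
accepted at ≥ 5000 px (ties break toward the topmost-leftmost bounding
box); the 180 rays span 360° at 2° spacing — the only arithmetic
consistent with both numbers — and are anchored at the *mask centroid*
(not the image center) for position invariance.

Ray counts are sampled at 1-px steps with **bilinear interpolation** of
the mask. With nearest-pixel sampling, a ray grazing a finger edge jumps
by tens of counts under sub-pixel centroid shifts, which makes single-frame
label flips unavoidable; interpolation makes the signature Lipschitz in
the centroid position at negligible cost.

Gesture models are per-user, trained from 35 segmented frames per gesture
collected in the same scene the test runs in (as a per-user calibration
would be); signatures are normalized with the same ⟨−1,1⟩ scheme as the
accelerometer features. A gesture event is a maximal run of at least two
consecutive identical frame labels; shorter runs are flickers and are
discarded entirely (they neither create events nor split the surrounding
run). Reports flag themselves unreliable when more than half of the
analyzed frames contain no valid hand.

The synthetic renderer draws rigid palm-plus-finger silhouettes
(intensity ~200) over a smooth textured desk (~60 ± 15) with per-frame
sensor noise and ±2 px placement jitter. Real camera footage adds
articulation, lighting changes, motion blur and true shadows that the
renderer does not model; the VTP results on synthetic frames validate the
pipeline's mechanics, not field accuracy.

## Numerical and interface choices

* Sessions are wide CSVs (`time_s` + one column per sensor axis, floats in
  g) with half-open `[start_s, end_s)` label intervals; one file holds
  sensors sharing one rate (the sampling rate is inferred from `time_s`).
  Samples outside ±6 g clamp with a logged warning (sensor saturation);
  strict mode turns this into an error.
* Frame counts: 1 + ⌊(N − N_w)/N_h⌋; filtering always precedes framing.
* Undefined-feature bookkeeping, normalizer clamping and all tie-breaks
  are deterministic and documented above.
* Every CLI run logs a provenance block (command, seeds, configs, package
  version) to stderr.

## Known limitations

* No resampling between 51.2 and 62.5 Hz; a session used for one
  classifier must be uniform in rate.
* The ANN uses fixed hyperparameters (no early stopping or validation
  split); it is a faithful re-creation, not a tuned baseline.
* Platt calibration on small, well-separated training sets yields weakly
  calibrated probabilities; one-vs-all arbitration near the decision
  boundary is correspondingly noisy.
* The synthetic generator and renderer trade realism for analyzability,
  as detailed above; no claims transfer to clinical data without
  re-evaluation.
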