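# Methods

This note records the models implemented by `hybridbci`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Signal model and preprocessing

Recordings are `channels × samples` matrices in microvolts at 128 Hz over
the 14-channel 10–20 subset of a consumer headset.  All band-pass
filtering uses 5th-order Butterworth designs: 8–30 Hz for motor imagery,
4–50 Hz for SSVEP, 1–20 Hz for P300 (the same filter family everywhere;
only the SSVEP path's order is dictated by convention, and we reuse it).
Offline/recording-level filtering is zero-phase (forward–backward,
`sosfiltfilt`); a causal single-pass mode is available for code that
wants real-time semantics.  Single 2 s windows are filtered with
Gustafsson's initial-condition method, which minimizes the edge
transients that otherwise dominate short-window filtering — without it
the noiseless SSVEP correlation saturates at ≈0.989 instead of ≈0.9998.

Windows are half-open `[start, start + width)`, sample indices 0-based.
Sliding windows of 2 s advance every 250 ms; the count follows
`floor((T − width)/step) + 1`.  Flash epochs span 0.6 s; 0.6 s × 128 Hz
= 76.8 samples is not an integer, so epoch length is fixed at
`floor = 76` samples (19 after 4× decimation), trading the final partial
sample for deterministic shapes.  Decimation 128→32 Hz uses a polyphase
FIR with line-extended edges, which preserves DC exactly on short
epochs.

I/O: EDF is read through `mne`; writing uses a built-in minimal EDF
writer (16-bit samples, one data record), whose round trip through the
mne reader doubles as a format check.  The CSV dialect has a `time_s`
column plus one column per channel; events live in a two-column sidecar
file `(sample_index, code)` for both formats.

## Synthetic EEG

The generators produce the *statistical structure each decoder assumes*,
not biophysically realistic EEG:

* background: `1/f^α` noise (α = 1, pink — the simplest EEG-like
  spectrum), zero mean, unit variance per channel, deterministic under a
  seed;
* motor imagery: an additive band-limited (8–13 Hz) Gaussian rhythm on
  FC5/FC6 (gain 1.0) and F3/F4 (gain 0.7); imagery trials attenuate its
  amplitude by the `attenuation` fraction (default 0.7) — amplitude
  attenuation of a non-phase-locked oscillation, matching the
  event-related-desynchronization concept;
* SSVEP: a random-phase sinusoid at the stimulus frequency added to
  O1/O2, optional weak second harmonic;
* P300: a positive half-cosine bump (width 0.2 s, peak 0.30 s after
  flash onset) with a parietal-dominant topography (P7/P8 largest),
  added after flashes of the favourite object; flashes are 250 ms apart
  in seed-randomized order with equal counts per object.  Exactly one
  favourite per stream by default; zero (or several) are permitted since
  each object's decision is an independent binary detection.

`snr` is a linear amplitude ratio (injected-component RMS over the
unit-variance background on the carrying channels).  No published SNR or
amplitude figures exist for this class of recording, so defaults (snr 1
for calibration-scale tests, 2–3 for "generous SNR" recovery tests) were
chosen once as values where the decoders operate well above chance but
below saturation.  Because the generators contain no artifacts, no
non-stationarity, no inter-subject variability and no volume-conduction
structure beyond the planted patterns, passing tests demonstrate
*algorithmic correctness and recoverability*, not expected accuracy on
real recordings.

## ERD decoder

Per-trial covariances are trace-normalized before averaging within each
class — standard CSP practice that removes trial-level amplitude
differences.  `fit_csp` solves `C_a w = λ (C_a + C_i) w` via
`scipy.linalg.eigh` and keeps the m = 2 largest- and smallest-eigenvalue
eigenvectors; a trace-scaled shrinkage (γ = 1e-6) is applied only when
the composite covariance is rank-deficient.  Eigenvector sign is fixed
by making the largest-magnitude component positive.  When all whitened
eigenvalues are within 0.05 of 0.5 the model is flagged
non-discriminative.  The classifier is a linear-kernel SVM (C = 1,
exposed); its raw margin is returned alongside the label so the hybrid
layer can log confidence.  Tests verify the implementation against an
independent whiten-then-diagonalize oracle to 1e-6 after sign alignment.

## SSVEP decoder

References contain one harmonic (sin/cos at f), rows mean-centred, with
duration equal to the 2 s analysis window.  The first canonical
correlation is computed from the two-block covariance formulation
`C_xx⁻¹ C_xy C_yy⁻¹ C_yx` with a relative ridge of 1e-9 on the
autocovariance blocks; tests pin it to a QR/SVD oracle at 1e-8 and check
invariance to invertible channel mixing and to reference phase.  Windows
reuse the 4–50 Hz artifact-reduction band; no narrower band is applied
before correlation.

## P300 decoder

`fit_xdawn` estimates the evoked response as the least-squares solution
of a stimulus-aligned design; for a single stimulus class with
epoch-aligned regressors this reduces to the ensemble mean of target
epochs, which is what is computed.  Filters solve `C_s w = λ C_x w`
(evoked covariance over pooled epoch covariance), keep the top 3
eigenvectors, and are checked against a whitening oracle.  Epochs
overlap (250 ms ISI < 600 ms span) and are scored independently on the
shared continuous stream.

The Bayesian LDA regresses targets ±1 with a zero-mean Gaussian prior;
MacKay's evidence updates for (α, β) iterate to relative tolerance 1e-6
(≤ 200 iterations), warning and returning the last iterate on
non-convergence.  With fixed hyperparameters the weights equal the ridge
solution with ridge α/β exactly, which the tests assert at 1e-8.  The
log evidence is tracked per iteration and is non-decreasing.

Per-object decisions: mean score across the object's flashes against a
threshold calibrated as the midpoint of the training class-mean scores
(0 is the fallback when calibration is disabled; whether per-subject
calibration or a fixed threshold is used online is a deployment choice —
both are supported).  Mean-score aggregation is what produces the
observed accuracy-vs-flash-count improvement.

## Arbitration and confirmation

The selector is trained on (ρ₁₂, ρ₁₅) pairs: a degree-2
polynomial-kernel SVM separates the ERD region (containing *both*
imagery and idle windows — both are outcomes of ERD operation) from the
SSVEP region, and a linear SVM splits left from right inside it.  The
12 Hz → left mapping is a configuration default; nothing forces it.

The fading rule: adoption at level 0, +1 per agreement, confirmation on
reaching level 4 (so five classifications — 1.0 s at 250 ms — is the
floor, verified exhaustively), −1 per disagreement.  A disagreement
arriving at level 0 *drops* the candidate and the next classification
adopts anew; this two-step replacement is what makes the worked
competition trace (L, L, then seven R's) confirm on the ninth input.
Idle (NONE) classifications decrement like any disagreement but are
never adopted and never confirmed, so idle noise can only delay or
cancel — never actuate.  State resets after each confirmation and on
mode transitions.

## Surrogate and closed loop

Angles are in degrees, counter-clockwise positive; positive head offset
is leftward.  The ERD switch toggles walking when head and body are
aligned within 9°, and otherwise starts an alignment turn during which
all commands are ignored; toggling (rather than start-only) is the
minimal semantics that also allows stopping, and a start-only flag can
be layered on.  Walking is continuous until toggled.  The toy camera
renders geometric colour blobs, not images — enough to exercise the
colour-filter detection, centre-of-gravity and central-zone logic, which
is the algorithmic content.  The central zone is the middle fifth of the
view in each axis, half-open `[0.4, 0.6)`.

The closed-loop runner advances the robot once per 250 ms classification
step (straight-line/constant-rate integration is exact at any step
size); `tick()` accepts arbitrary dt for finer simulation.  The
recognition episode is timed as 4 s rest, flash phase
`(n_objects·flashes − 1)·0.25 + 0.6` s, then 2 s result display.

## Evaluation

Cross-validation is stratified 10-fold at the trial level with the whole
fitting pipeline inside each fold.  The Wolpaw ITR uses
`log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))` bits per decision — clipped
to zero below chance, since the N = 2 form is symmetric about 0.5 — at
30 decisions/min (one per 2 s window), which reproduces the published
per-subject rates of this system class from their printed accuracies.
Navigation metrics reduce trajectory logs: a nominal "step" is one
second of continuous walking or turning; explored angle sums the 3°
head-turn quanta; transitions count boundaries between runs of
exploration (head-turn) and navigation (switch) confirmations.
Multi-run aggregation uses the arithmetic mean and sample SD (n−1).

## Problem sizes used in the test suite

Calibration-scale checks use 20 trials per class (2 s windows), mirroring
a realistic 20-repetition training session; recovery checks use 30
trials or flashes per condition; recognition accuracy is measured over
40 independent streams; monotonicity checks use 3-point SNR/flash grids.
These sizes are the package's own trade-off between statistical margin
and a test suite that runs in seconds.

## Known limitations

* Generators are stationary and artifact-free; accuracy figures on them
  exceed anything attainable with real low-cost recordings.
* The EDF writer covers the subset of the format the toolkit needs
  (uniform rate, one record, 16-bit) — it is not a general-purpose
  archival writer.
* Multi-class CSP, filter-bank CCA, row/column P300 spellers and online
  adaptation are out of scope.
* The surrogate is kinematic: no gait dynamics, no camera noise, no
  network transport.
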