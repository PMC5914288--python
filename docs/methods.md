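# Methods

This note documents the models implemented in `gaitbci`, the defaults and
the reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical choices that matter.

## Protocol and data model

A trial is four consecutive phases — stand (120 s), walk (900 s), walk+BCI
(300 s), stand (120 s) — sampled at 100 Hz, so one trial carries 24 min of
signal and a three-trial subject 72 min. EEG/EOG and joint angles are
recorded in pairs: the loader enforces equal sample counts and pairwise
aligned timestamps across `eeg.txt` and `joints.txt` and treats any
mismatch as a hard synchronization error. Text files accept any run of
whitespace on read and are written tab-delimited, UTF-8, with six
significant digits for physical quantities and full float precision for
timestamps; this makes write → read → write the identity at the byte level
for files the package produced.

The 64-channel layout is a standard 64-electrode cap with T7/T8 relocated
to FCz/AFz and TP9/TP10/FT9/FT10 repurposed as periocular EOG. `eeg.txt`
itself carries no labels; they come from the impedance-file index order,
with positional `ch01..ch64` as the standalone fallback.

## Goniometer calibration

Per joint, the mapping is affine with slope x0/x: zero-posture reading ↦
0°, calibration-maximum reading ↦ x0 (90° hip/knee, 43° ankle — the ankle
cannot reach 90° dorsiflexion, hence the inclined platform). Extension
beyond the standing zero maps through the same line to negative angles;
readings outside the calibrated range are extrapolated, not clipped, and
flagged with a warning. A zero measured range is rejected as a degenerate
calibration.

## Gait segmentation

Cycles span successive flexion maxima of one joint trace (right hip by
default — the BCI-controlled leg). Before peak picking the trace is
smoothed with a centered 0.15 s moving average: goniometer noise at 100 Hz
otherwise produces spurious sample-level maxima that survive any purely
prominence-based criterion. Peaks must be separated by at least
0.6 / cadence_upper seconds (default bounds 0.4–1.5 Hz) and have prominence
of at least 10% of the trace's inter-quartile range, which makes the
segmentation deterministic, robust to additive noise and exactly invariant
to amplitude scaling. n peaks yield n − 1 cycles; flat traces yield none.

## H∞ ocular-artifact filter

The filter removes the component of each EEG channel explained by the
2-element EOG reference (vertical TP9−TP10, horizontal FT9−FT10). Defaults
are γ = 5, q = 1e-10, initial weight covariance p0 = 1. The covariance
recursion is implemented in its standard adaptive-noise-cancellation form
(matrix inverses as written above); a `literal_equations` flag retains the
no-inverse reading of the update for comparison. Two properties pin the
implementation down: with a zero reference the filter is a bit-exact no-op,
and as γ → ∞ it coincides with q-regularized recursive least squares
(verified to 1e-6 against an independently coded RLS).

Because P̃ and P depend only on the shared reference, one 2×2 covariance
recursion serves all 60 channels; only the weight vectors are per-channel.
The γ⁻² correction defines an indefinite metric, and P̃⁻¹ − γ⁻² r rᵀ can
lose positive definiteness at isolated samples — it necessarily does at
t = 0 with p0 = 1 and a ~100 µV reference, and again at the first large
blink. Resetting the whole state there would discard the learned weights
every time an artifact arrives, so such steps instead fall back to the
uncorrected gain P = P̃ (the RLS gain) and are counted in the filter state;
a full reinitialization is reserved for non-finite corruption. 2×2
inverses are closed-form; positive definiteness is checked via determinant
and trace.

## Feature extraction

Features are the amplitude fluctuations of slow cortical potentials: a
causal 2nd-order Butterworth band-pass at 0.1–3 Hz per channel, followed by
a causal per-channel running z-score (exponential window, 30 s time
constant, 1 µV² variance floor so that silence maps to zero and the
early-stream variance estimate cannot explode), optionally followed by a
lag embedding (L delayed copies at a configurable spacing, dimension
C·(L+1)). Everything is strictly causal: truncating the input truncates
the output.

Default: all 60 EEG channels, no lag embedding. Lags are supported but off
by default — with 10 lags the observation dimension reaches 660, making the
per-sample innovation solve and the per-minute refits disproportionate for
a 100 Hz real-time loop, and an instantaneous linear readout already
captures the coupling the state-space model assumes. Which features the
original real-time system used (lags, normalization, channel subset) is not
recoverable here; these defaults are this package's choices, all
configurable.

## State-space decoder

The filter state is the six joint angles in degrees. `kf_predict` /
`kf_update` implement the standard recursion; covariances are symmetrized
every step, and a singular innovation covariance is damped with a logged
diagonal (1e-8 × mean diagonal) rather than failing. The unscented variant
uses scaled sigma points (α = 1e-3, β = 2, κ = 0), redraws sigma points
from the predicted density before the observation transform, and jitters
and retries once if the covariance square root fails; with linear models it
matches the Kalman filter to 1e-6 over 1000 steps. The neural model is
linear by default with an optional elementwise-quadratic term
z = H x + H₂ x² + b, which the unscented transform handles without
re-derivation (verified against Monte-Carlo propagation).

CLDA fits F by least squares of x_t on x_{t−1} and H (with a bias column,
on by default, absorbing feature offsets) by least squares of features on
states; Q and R are the residual covariances. Rank-deficient regressors
fall back to ridge with penalty 1e-6 · trace(XᵀX)/p, logged. Refits happen
at every full minute of the walk phase over a growing buffer (a sliding
window is available); the new model is blended with the previous one as
λ·new + (1−λ)·old with λ = 0.5 by default, and the first fit is taken
as-is. Whether Q and R are refit each cycle or held is configurable
(refit is the default). A 15-minute walk yields exactly ⌊900/60⌋ = 15
update events; the 15th refit coincides with the phase boundary and uses
walk data only. After that boundary the model is frozen — the run records
the model at the transition and at the end so the freeze is checkable
element-wise.

During walk the displayed (P) columns mirror the measured (G) columns;
during walk+BCI the right-leg P columns carry the decoder output while the
left-leg P columns keep mirroring, providing the visual ground truth the
protocol prescribes. The filter starts from the measured posture at the
phase boundary with covariance Q + 1e-6·I.

## Evaluation

Per-cycle Pearson r (mean removal happens inside the correlation, no
detrending) between the measured and predicted trace of one joint, right
hip by default; cycles shorter than 3 samples or with zero variance are
omitted with a warning. "Steps" are equated to the segmented gait cycles.
Phase comparison reports medians and a two-sided Wilcoxon rank-sum p-value
— the r distributions are non-Gaussian and cycles are not paired across
phases, so a rank test is the defensible default. Impedance QC counts
channels above 60 kΩ per phase and reports means ± sd and per-channel
before→after deltas. Published real-data reference points for this style
of session (median r ≈ 0.64 walk / 0.53 walk+BCI; ~5% of channels above
60 kΩ after recording) are documentation only: they require the original
recordings and are not asserted anywhere in this package's tests.

## Synthetic generator

The generator emulates the structure the pipeline assumes, with every
condition fixed in `SynthConfig`:

* **Kinematics** — per-joint-class Fourier templates (fundamental +
  2nd harmonic of a 0.75 Hz stride, consistent with 0.45 m/s slow walking)
  with hip/knee/ankle-appropriate ranges inside [0, 90]/[0, 90]/[−20, 43]°,
  left leg half a stride out of phase; stand phases hold a near-constant
  posture with a 1.5 s smoothstep transition. Measured columns add 0.5° rms
  Gaussian noise and 0.1°/min random-slope drift. Predicted columns mirror
  measured ones — decoded output comes from the decoder, not the generator.
* **EEG** — a known forward model H* (i.i.d. Gaussian rows) applied to the
  delta-band-limited joint trajectories, on top of 1/f background noise at
  20 µV rms, scaled so the coupled component sits `snr_db` above the
  in-band background (0 dB default; the `high-snr` preset uses +20 dB, the
  `noisy` preset −10 dB, `null` removes the coupling). EOG leaks into EEG
  channels with random per-channel coefficients (scale 0.3 by default).
* **EOG** — Poisson blinks (12/min, 300 ms raised-sine bumps, ~120 µV,
  split +0.75/−0.25 across the vertical pair) and Poisson saccade steps
  (8/min, ±30 µV, split across the horizontal pair) plus 2 µV sensor noise.
* **Files** — the full conductor event stream (treadmill 10, CLDA start/stop
  8, one 13 per scheduled refit, 16 thinned to 1/s by default, quit 9),
  log-normal impedances (median 20 kΩ σ=0.5 before, 9 kΩ σ=0.9 after,
  chosen to resemble typical gelled-electrode sessions), and an idealized
  spherical 10-10 digitization whose Cartesian and polar coordinates agree
  by construction (1 mm digitizer jitter). Montage and impedances are drawn
  per subject-day, so trials 1 and 2 share them exactly.

Determinism: all randomness flows from `numpy.random.default_rng` seeded by
(seed, subject, day/trial); equal seeds give byte-identical folders.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: volume-conducted motion artifacts, EMG and
line noise, non-stationary electrode drift, cadence variability and
step-to-step kinematic irregularity, genuinely nonlinear or lagged
gait–EEG coupling, and realistic (weak, non-stationary) coupling strength.
The high-SNR end-to-end result (median per-cycle r ≥ 0.8) validates the
pipeline's correctness, not achievable performance on human recordings.

One identifiability note: the six phase-locked periodic trajectories span
only a 4-dimensional function space (sine/cosine of two harmonics), so
CLDA can recover H* only on that excited subspace — the top four canonical
correlations between fitted and true H are ≥ 0.9 on high-SNR sessions,
while the remaining directions are unconstrained by the data. Recovery of
the full matrices to 5% relative Frobenius error is instead exercised on
persistently exciting linear-Gaussian buffers.

## Problem sizes

The test suite runs most checks on shortened protocols (5 s stand / 130 s
walk / 20 s walk+BCI / 5 s stand) that still contain two refit intervals
and dozens of gait cycles; the end-to-end acceptance check runs one
full-duration (24 min) high-SNR trial through generation, H∞ cleaning,
CLDA and decoding. Oracle comparisons use 2–6-state toys, 1000-step
trajectories and 10⁵-draw Monte-Carlo propagation.

## Known limitations

* The `.bvct` schema is a minimal, documented assumption (CapTrak-style
  node names); real digitizer exports may differ and unknown nodes are
  ignored rather than validated.
* Whether deposited joint angles are already calibrated is ambiguous; the
  loader exposes the joint factors so the map can be inverted, but applies
  no transformation itself.
* The walk-phase P columns mirror G exactly, so walk-phase per-cycle r is
  1 by construction in decoded output; cross-phase comparisons on synthetic
  sessions are therefore one-sided by design.
* No real-time OS guarantees: streaming semantics (causality, O(1) state
  per sample) are tested, wall-clock deadlines are not.
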