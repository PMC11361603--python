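# Methods

This note documents the models implemented in `smanet`, the parameters that
matter, the synthetic data the test suite runs on, and the numerical
choices made where the design was genuinely open. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Problem setting

Scalp EEG during convulsive seizures is a mixture of cortical rhythms and
cranial/facial muscle activity (EMG). The package separates the two per
channel, then quantifies how coherently the muscle-like part (SMA, scalp
muscle activity) behaves *across* the electrode array. The working
hypothesis is physiological: convulsions driven from brainstem networks
recruit cranial muscles more synchronously, so array-wide SMA phase
coherence — summarised at 1–12 Hz and 13–30 Hz — carries information about
SUDEP risk. The package provides the measurement chain and a propensity
classifier; it does not adjudicate SUDEP itself.

## Preprocessing

Recordings at native rates 200–512 Hz are polyphase-resampled at the exact
rational ratio to **512 Hz**, then low-pass filtered at **100 Hz** with a
zero-phase windowed-sinc FIR (Kaiser design, 140 dB ripple spec, cutoff
110 Hz, transition 100→120 Hz, applied forward-backward). The FIR was
chosen over an IIR low-pass for two properties the chain relies on:
stopband attenuation beyond 40 dB at 120 Hz, and a passband flat to ~1e-7
so that re-applying the chain to already-preprocessed data is a no-op away
from edge transients. Zero-phase filtering everywhere is deliberate: every
downstream quantity is a phase statistic, and phase distortion in
preprocessing would bias it. Data are held in microvolts. The first and
last second of each record are treated as filter transient and excluded
from temporal averages downstream.

## SSA extraction

Each channel `x` (length N) is embedded in an L × (N−L+1) Hankel trajectory
matrix, decomposed by thin SVD, and each rank-1 term is hankelized
(anti-diagonal averaging) into a component series; with elementary grouping
the channel splits into exactly **L = 30** components that sum to the input
to machine precision. L = 30 at 512 Hz is a ~59 ms window: long enough to
resolve the rhythm/EMG autocorrelation contrast, short enough that each
component stays nearly narrowband. The window is applied after upsampling,
so the component count is rate-independent. Rank-1 hankelization is
computed as a convolution of the singular vectors divided by anti-diagonal
lengths, keeping the per-channel cost at O(L N log N).

Records longer than 60 s are decomposed in 60 s blocks joined by a 1 s
linear cross-fade. SSA is linear, so the cross-fade preserves the exact
reconstruction identity; component identity across seams is approximate,
which only matters within 1 s of a seam.

Components are notch-filtered (zero-phase biquads, Q = 30) at 60 Hz and
every harmonic below Nyquist (60/120/180/240 at 512 Hz) *before*
classification, so powerline energy cannot masquerade as broadband muscle
activity. By linearity the SMA/EEG partition still sums to the
notch-filtered input exactly.

**Classification.** Each component's lag-1 autocorrelation
R = corr(s(t), s(t−1)) is compared to a threshold: a narrowband component
at frequency f has R ≈ cos(2πf/fs) — above 0.93 for anything below 30 Hz
at 512 Hz — while broadband EMG-like components fall well below.
`R < threshold` (strict) sends a component to SMA; equality retains it as
EEG, and zero-variance components are defined to have R = 1 (DC/trend is
not muscle). The default threshold is **0.8**.

**Threshold tuning.** `tune_threshold` sweeps 0.50–0.95 in 0.05 steps over
interictal control segments (nominally 62 s; ≥30 s accepted with a
warning). For each candidate it extracts SMA on the frontal probes (Fz,
Fp1, Fp2 — closest to facial muscles), computes the wavelet phase coherence
between extracted SMA and the *raw* electrode, and averages it over time
and over 1–30 Hz versus 31–100 Hz. A good threshold captures everything
EMG-like (high coherence with the raw electrode above 30 Hz) without
pulling in EEG rhythms (which would raise the 1–30 Hz coherence), so the
selected value maximises `WPC(31–100) − WPC(1–30)`; exact ties break toward
0.8, then toward the smaller value. Ties are not hypothetical: thresholds
falling in a gap of the component-R distribution extract identical signals
and score identically. The 50–70 Hz log power ratio of extracted over
retained signal is reported alongside as a diagnostic, mirroring the
power-spectral view of the same choice. (The band split uses 31–100 Hz;
band edges are inclusive on the 1 Hz grid throughout.)

## Coherence

**Phase.** Instantaneous phase comes from a complex Morlet CWT with centre
frequency parameter ω₀ = 6 (the standard trade-off for phase estimation:
~6 cycles of temporal support, σ_f = f/6 spectral width) on a 1 Hz grid,
1–100 Hz. The wavelet family is the package's choice; it is the de facto
standard in the phase-coherence literature. Samples within two Gaussian
widths (~2 cycles) of a record edge are masked as cone-of-influence, and a
frequency with fewer than three cycles in the record is masked entirely.
Masked samples are *excluded* from every average rather than zero-filled —
zero-filling biases coherence toward 0.

**WPC.** For a channel pair, coherence at frequency f is the resultant
length of the phase difference, computed in sliding windows of
`max(1 s, 4 cycles of f)` with 50% overlap, then averaged (time first, then
frequency) over the ictal interval and band. Windowing is an open design
point — the time average could equally run over the whole seizure — and the
window rule matters: with 1 s windows, two independent but *narrowband*
signals at the same frequency show a substantial coherence floor, because
their phase difference drifts slowly relative to the window. This floor is
common to all recordings processed identically, so group contrasts survive
it, but absolute WPC values must be read as window-rule-dependent. The
n:m phase-phase coupling map assigns each (f_slow, f_fast) cell the integer
ratio n:m closest to f_fast/f_slow with m ≤ 4.

**Averaging chain.** 19 electrodes give 361 ordered pair matrices (mirror
pairs share storage; self pairs are identically 1). Per band: pair value →
per-electrode mean over the 18 partners (self excluded) → per-seizure mean
over the 19 electrodes.

**Pipeline grid.** The network stage computes coherence on a 1–30 Hz grid
(`wpc_max_freq`), since both summary bands end at 30 Hz; the full 1–100 Hz
grid is used where the high band is the object of interest (threshold
tuning, coupling maps).

## Risk model

A logistic model on the standardized per-seizure features
(WPC 1–12 Hz, WPC 13–30 Hz) gives a propensity score in [0, 1]. The fit is
effectively unpenalised maximum likelihood; if the fitted direction
separates the classes perfectly — likely at n ≈ 25 — the likelihood
diverges and the fit falls back to a small ridge (1e-6) with a warning.
ROC/AUC uses trapezoidal integration, equal to mid-rank pair concordance;
the decision threshold is the accuracy-optimal operating point.
Leave-one-out cross-validation scores each seizure with a model trained on
the rest, pools the scores into one ROC, and repeats over 10 rounds that
differ only in training-row order; LOO is deterministic, so the rounds
coincide under this solver and the mean AUC is reported for transparency.
The unit of cross-validation is the seizure; because multiple seizures per
patient leak patient identity across folds, a patient-grouped variant
(`group_by_patient=True`) is provided. Group comparisons are reported as
estimation statistics: mean difference with a percentile-bootstrap 95% CI
(default 5000 resamples), not p-values.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes:

- **Rhythms**: narrowband stochastic oscillators — band-limited noise of
  1.5 Hz bandwidth around each rhythm frequency (defaults 3, 8, 11, 21,
  27 Hz), independent per channel. Stochastic rather than pure tones for a
  structural reason: two pure tones at the same frequency are *always*
  perfectly phase-coherent (a constant offset does not decohere a
  resultant), which would make retained-EEG coherence trivially 1 and
  contaminate the SMA bands via spectral leakage. Independent narrowband
  processes decohere over ~1/bandwidth.
- **EMG-like source**: white noise band-passed to 40–150 Hz with gentle
  2nd-order Butterworth skirts — dominant power above 50 Hz with a small
  low-frequency tail, like surface EMG; no motor-unit physiology.
  Per channel: `κ · shared + √(1−κ²) · private`, so the mixing weight
  **κ ∈ [0, 1]** *is* the inter-channel muscle coherence dial the
  downstream analysis measures.
- **Amplitudes**: rhythm:EMG RMS ≈ 1:2 in "ictal" state (20 vs 40 µV),
  2:1 interictally (30 vs 15 µV), mimicking ictal muscle prominence.
- Cohorts assign κ per group (defaults 0.8 vs 0.2) with per-recording
  seeds derived from a master seed; an optional (f_slow, ratio) term adds
  an exact n:m-coupled tone pair for coupling-map validation.

What passing tests on this generator show: the chain separates spectrally
disjoint sources, measures the built-in coherence dial monotonically, and
the classifier recovers a group difference that is genuinely present. What
they cannot show: performance on real ictal EEG, where muscle and cortical
spectra overlap, electrodes move, and the SUDEP effect size is unknown.

**Problem sizes.** The validation cohort is 2 × 12 seizures of 26 s at
512 Hz (4 subjects × 3 seizures per group) and tuning uses three 62 s
controls on the three probe electrodes — sizes chosen so the full suite
re-runs in minutes on a single CPU while every stage operates in its
intended regime.

## Numerical choices and degenerate inputs

- SSA singular values below 1e-12 of the largest are zeroed; their
  components are exact zero series. A constant series yields one mean-trend
  component plus zeros, not an error.
- Lag-1 autocorrelation of a zero-variance series is defined as 1
  (retained as EEG).
- Coherence entries with no jointly valid samples are NaN and excluded
  from averages; wavelet coefficients that are exactly zero carry no phase
  and are masked.
- The EDF writer is a minimal 16-bit implementation (one record per
  second, per-channel physical scaling); quantisation error is the
  physical range / 65535. Epochs travel in a YAML sidecar for delimited
  files; EDF+ annotations are out of scope.
- All stochastic steps (generator, bootstrap, CV round order) take
  explicit seeds; identical config + inputs give byte-identical outputs.

## Known limitations

- The autocorrelation threshold is global, not per patient or per channel.
- Seizure-level LOO leaks patient identity; use the patient-grouped
  variant when patients contribute multiple seizures.
- Absolute WPC levels depend on the windowing rule (see above); compare
  only values computed with identical settings.
- No high-frequency-oscillation analysis (>100 Hz), no re-referencing or
  artifact rejection beyond the notch, no real-time mode.
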