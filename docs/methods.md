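# Methods

This note documents the models, rules and numerical choices behind
`cwtcardio`, and what the synthetic-data validation does and does not show.

## Signal model and device constants

The target device is a chest-strap pulsimeter streaming three frame kinds:
ECG waveform frames (63 samples per frame, one sample every 4 ms, i.e.
250 Hz), breathing-waveform frames (18 samples per frame, one sample every
56 ms) and summary frames with scalar vitals.  The ECG ADC grid has a
resolution of 0.013405 mV over 0–50 mV.  The companion skin-conductance
(SCR) board samples at 4 Hz through an ADC with 0.573 mV steps and a
2.35 V ceiling.

Two payload conventions are not fixed by the device documentation we model
and are therefore declared here: waveform payloads are decoded as unsigned
16-bit little-endian ADC counts, and the heart rate in summary frames is
read from payload bytes 12–13 as an unsigned 16-bit integer, little-endian
by default with a flag to flip (`hr_byte_order="big"`), since wearable
payloads are conventionally little-endian but the layout drawing alone
cannot settle it.

## R-peak detection

Detection rests on the continuous wavelet transform

    C(a, b) = a^(-1/2) ∫ x(t) ψ*((t − b)/a) dt

with a Coiflet-5 mother wavelet.  Time is measured in samples, so the
scale `a` is dimensionless; the integral is evaluated as a discrete
correlation against the cascade-sampled wavelet.  The L2 prefactor
`1/sqrt(a)` is used; the choice only rescales coefficients and cancels in
the normalized detection stage.  Near the end of a record the kernel
overlaps the signal only partially, which breaks the wavelet's zero-mean
cancellation and can ring; the detection path therefore mirrors the signal
past the last sample (`pad="reflect"`), while the bare `cwt` function
keeps the literal truncated integral so it matches the defining sum
exactly.

The per-sample detection series is the selected scale's coefficients
squared (sign-invariant, peak-sharpening; `abs` is available as an
alternative strategy) with the wavelet's group delay of `a · t_peak`
samples compensated, where `t_peak` is the location of the wavelet's
energy maximum.  The analysis scale defaults to the crest-factor maximizer
(peak-to-mean ratio of the detection series) over an integer grid a =
2…10, evaluated on the first 30 s of the record; at 250 Hz this grid
spans QRS-like matched durations and in practice the selector lands on
small scales for clean signals and drifts larger as broadband noise grows.
The scale can be pinned explicitly for reproducibility across records.

Thresholding operates in non-overlapping 5 s windows (the final partial
window is processed when at least 1 s long), each extended by a 0.3 s
margin for peak finding so beats at window seams are not truncated; a peak
is attributed to the window containing it.  Within a window the series is
normalized to maximum 1 and local maxima at least 200 ms apart (a
physiological refractory floor) and above a 0.05 normalized floor become
candidates.  Candidate amplitudes are reported on the |C| scale (square
root of the normalized squared series) so that the classification bands
act on amplitude ratios.  The per-window reference is the mean candidate
amplitude (`threshold_mode="maxima_mean"`, default) or the window maximum
(`"window_max"`); candidates above 60 % of the reference are R waves,
candidates in (30 %, 60 %] are provisional extrasystoles, lower ones are
dropped.  The bands partition (0.3, 1.0] so every retained candidate gets
exactly one class.  The maxima-mean variant is the default because a beat
whose amplitude is 45 % of its neighbours should sit inside the 30–60 %
band regardless of how many beats the window holds.

Windows that contain no beats must stay silent even though normalization
would amplify their noise floor to 1.  A signal-quality gate handles this:
a window is processed only when the squared series' max/median ratio is at
least 60.  QRS-bearing windows are impulsive (ratios in the hundreds to
millions, because the median sits on the inter-beat floor), while windows
of pure broadband noise stay below ~50; the gate was placed between the
two regimes with about a factor-of-two margin on each side.  The gate
compares a window to itself, so amplitude-scale invariance of the detector
is preserved exactly.

## Beat classification and arrhythmia rules

Two ratio rules act on the detected beat times `t(i)`:

* Premature beat: `(t(i) − t(i−1)) · 2.2 < t(i+1) − t(i)` (strict).  A
  premature beat shortens the interval before it and is followed by a
  compensatory pause, so the stretched preceding interval fits inside the
  following one.  This rule re-classifies beats whose amplitude exceeded
  the 60 % band; beats inside (30 %, 60 %] are extrasystoles by amplitude
  alone; the first and last beats, untestable by timing, keep their
  amplitude class.
* Arrhythmia: the interval ending at `i` differs from its predecessor by
  at least 30 % in either direction, `RR(i) ≥ 1.3 · RR(i−1)` (inclusive)
  or `1.3 · RR(i) ≤ RR(i−1)` (inclusive).  The shortening inequality is
  read symmetrically to the lengthening one.  Flags are attached to the
  interval-ending beat index; contiguous flags additionally merge into
  episode spans with zero-gap merging.

Both rules compare ratios only, so classification is invariant to time
shifts and positive time rescaling, which the property suite checks, along
with exact agreement with a literal per-index re-evaluation of the
inequalities on random beat trains.  The arrhythmia rule runs on raw RR
intervals; the Hermite-resampled series is for reporting and plotting
only.

## Heart-rate variability

The RR series anchors each interval at its ending beat.  Uniform
resampling uses shape-preserving piecewise-cubic Hermite interpolation
(PCHIP via SciPy): it passes through every knot and cannot overshoot on
monotone segments, unlike a natural cubic spline — the test suite
demonstrates the spline overshooting on the same knots as a contrast
oracle.  The default resample rate is 4 Hz, matching the SCR channel so
the two can be plotted on one grid.  Window statistics use the raw
(non-resampled) intervals: sample mean and sample standard deviation with
the n−1 denominator (a single interval reports SD 0).  A `units="bpm"`
toggle converts intervals to instantaneous heart rate first, since
published variability tables are sometimes printed in either unit without
labels.

## SCR stress classification

The SCR front end is a voltage divider, `Vo = R2/(Rs + R2) · Vcc` with
R2 = 890 kΩ; sweating lowers the skin resistance `Rs` and raises `Vo`.
The supply `Vcc` is configurable with default 1.775 V: the two published
voltage–resistance anchor points imply slightly different supplies
(0.136 V at 10 MΩ → ≈1.664 V; 1.755 V at 10 kΩ → ≈1.775 V), and the
low-resistance anchor was adopted because it pins the scale where stress
measurements actually live.  The inverse map `Rs = R2 (Vcc − Vo)/Vo`
round-trips to machine precision on (0, Vcc).

Stress-vs-relax classification is strictly per subject — baseline skin
conductance varies too much across people for a shared threshold — using a
C4.5-style binary decision tree grown by maximizing the information gain
ratio over midpoint thresholds between sorted distinct feature values.
Defaults: instantaneous voltage as the only feature (per-sample
classification; the first difference times the sampling rate is available
as a `slope` feature), unpruned growth with `min_leaf = 2`, ties broken
toward the lower threshold and then the lower feature index, so training
is deterministic given the data.  Reduced-error pruning against a labeled
validation record is provided as an optional post-pass.  ADC quantization
is applied when synthesizing signals, never when analyzing: the analysis
accepts continuous voltages.

Protocol labeling: during a Stroop (color-word interference) task all
in-task samples are stress; the relax reference is the first 55 s, the
last 60 s, or a custom span (one subject was calm only between 15 and
55 s).  In the annoying-sounds protocol only sounds the subject reported
reacting to are labeled stressful, each over a 15 s response span —
reactions are subjective, so the schedule makes them explicit inputs
rather than guessing them from the signal.

## Reference evaluation tables

`cwtcardio.data/reference_tables.json` bundles the published per-user
confusion-matrix counts and printed statistics from the validation study
of this detector family, as regression fixtures for the statistics layer.
Notes on that table set, handled explicitly here:

* The column printed as "Precision" equals overall accuracy
  `(TP+TN)/total`, not positive predictive value; both statistics are
  exposed under unambiguous names (`accuracy`, `ppv`).
* True negatives for beat detection are counted at sample level, so TN is
  on the order of the record length in samples.
* The printed "Correct"/"Incorrect" rows follow from the counts to within
  0.02 percentage points (the print mixes half-up rounding and
  truncation); the "Error"/"Success" rows do not follow from the counts at
  all (they appear to be a per-class aggregate of the original toolchain)
  and are therefore carried as published inputs, never recomputed.
* One R-wave table has a blank FN cell; the printed sensitivity of 1
  implies FN = 0, which is what the fixture stores.
* The headline 99.42 % figure is the unweighted mean of the twelve
  per-user sensitivities.

## Synthetic data: what it emulates, and what it does not

The ECG generator places a template beat — Gaussians for P (0.2 relative,
80 ms FWHM, −160 ms), Q (−0.1, 20 ms, −30 ms), R (1.0 ≙ 1 mV default,
25 ms), S (−0.15, 25 ms, +30 ms) and T (0.3, 120 ms, +220 ms) — on an RR
schedule at 250 Hz, first beat at 0.5 s.  Options add white noise,
sinusoidal baseline wander, Gaussian RR jitter, stretched-interval
arrhythmia episodes, and premature beats with reduced amplitude and a full
compensatory pause (the beat after the extrasystole lands where it would
have anyway, so the two surrounding intervals sum to twice the nominal
RR); a prematurity fraction below 1/2.2 makes the timing rule fire by
construction.  The SCR generator sums linear-rise/exponential-decay
response kernels on a drifting baseline with optional noise and ADC
quantization, labeling response spans as stress.

All randomness flows from the single spec seed through one
`numpy.random.Generator`; there is no hidden global state, and identical
specs produce bit-identical output.

These generators have realistic scales but idealized shapes: no
respiratory modulation, electrode motion artifacts, morphology drift,
muscle noise, or tonic/phasic SCR decomposition.  Passing the closed-loop
suites therefore shows that the implementation is faithful to its rules
and robust to the modeled disturbances (additive white noise, baseline
wander, amplitude scaling), not that the detector attains the published
sensitivities on real recordings — the study's raw recordings are not
deposited, so those numbers are validated at the arithmetic level (counts
→ statistics) rather than re-measured from signals.

## Problem sizes and numerical choices

* Detection sweeps use 60 s records at 50–120 bpm; the acceptance script
  runs 10 seeds per rate and the test suite 20 seeds at the rate extremes,
  sizes chosen to exercise every window-count regime while keeping the
  whole validation in seconds.
* Beat scoring matches detections to truth greedily in time order within
  ±50 ms (the tolerance is a scoring choice, about half a refractory
  period); for sorted lists with a uniform window this greedy matching is
  cardinality-optimal, which a maximum-bipartite-matching oracle confirms
  on random instances.
* Interpolation knot-exactness is asserted to 1e−12; the divider
  round-trip to 1e−9 relative over 10 kΩ–10 MΩ.
* The two-Gaussian tree benchmark (relax 0.68 V, stress 0.73 V, σ = 15 mV,
  n = 400) has its Bayes boundary at the midpoint 0.705 V by symmetry;
  the learned root threshold is required to land within ±15 mV (one σ).
* The Stroop-ordering simulation uses RR jitter SD 0.08 s at rest vs
  0.04 s in-task (the published per-user SDs span 0.03–0.15 s), 55 s rest
  vs 180 s task segments, 100 sessions.

## Known limitations

* The coefficient-modification stage and the analysis scale of the
  original pipeline are not recoverable from its description; both are
  exposed as strategies/config here and the defaults are this package's
  own choices.
* The exact frame payload layout beyond the documented timing constants
  and heart-rate byte offsets is not modeled.
* Single-lead only; no QRST delineation, no frequency-domain HRV, no
  cross-subject stress generalization, and no replication of
  morphological beat typing beyond the two ratio rules.
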