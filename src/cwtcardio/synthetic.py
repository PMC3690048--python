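"""Annotated synthetic ECG and SCR generators.

Every detector in this package is validated against signals with known
ground truth.  The ECG generator places template PQRST complexes (piecewise
Gaussians) on an RR schedule with optional jitter, premature beats
(extrasystoles), arrhythmia episodes, white noise and baseline wander; the
SCR generator sums stimulus-locked response kernels (linear rise,
exponential decay) on a drifting baseline.  All randomness flows from the
single seed in the spec object, so a given spec reproduces its output
bit-for-bit.

The PQRST template is a declared stand-in for real recordings: it has a
realistic R amplitude (about 1 mV), P/T waves and Q/S notches, but no
respiratory modulation, electrode artifacts or morphology changes.  An
inserted extrasystole is premature (its RR fraction configurable), has
reduced amplitude, and is followed by a full compensatory pause (the next
beat lands where it would have without the premature one, i.e. the two
intervals around the extrasystole sum to twice the nominal RR), which is
exactly the signature the downstream timing rules key on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import (
    ECG_FS_HZ,
    ECG_RESOLUTION_MV,
    SCR_ADC_RESOLUTION_V,
    SCR_ADC_VMAX_V,
    SCR_FS_HZ,
    ECGRecord,
    SCRRecord,
)

__all__ = ["ECGSimSpec", "SCRSimSpec", "gen_ecg", "gen_scr"]

#: PQRST template: (relative amplitude, offset from R in s, FWHM width in s).
ECG_TEMPLATE = (
    (0.20, -0.160, 0.080),   # P
    (-0.10, -0.030, 0.020),  # Q
    (1.00, 0.000, 0.025),    # R
    (-0.15, 0.030, 0.025),   # S
    (0.30, 0.220, 0.120),    # T
)
FIRST_BEAT_S = 0.5
END_MARGIN_S = 0.3


@dataclass
class ECGSimSpec:
    """Recipe for a synthetic annotated ECG.

    ``extrasystoles`` lists ``(beat_index, amplitude_ratio,
    prematurity_ratio)`` tuples: the beat at that index of the nominal
    schedule arrives after only ``prematurity_ratio`` of the nominal RR,
    scaled by ``amplitude_ratio``, and is followed by a full compensatory
    pause.  A prematurity ratio below 1/2.2 guarantees the premature-beat
    timing inequality fires at that beat.  ``arrhythmia_episodes`` lists
    ``(beat_index, rr_multiplier, length_beats)`` runs of stretched or
    shortened intervals.
    """

    duration_s: float = 60.0
    fs: float = ECG_FS_HZ
    hr_bpm: float = 75.0
    amplitude_mv: float = 1.0
    rr_jitter_sd_s: float = 0.0
    extrasystoles: list = field(default_factory=list)
    arrhythmia_episodes: list = field(default_factory=list)
    noise_sd_mv: float = 0.0
    baseline_wander: tuple | None = None   # (freq_Hz, amplitude_mV)
    quantize: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.hr_bpm <= 0:
            raise ValueError("duration_s, fs and hr_bpm must be positive")
        if self.rr_jitter_sd_s < 0 or self.noise_sd_mv < 0:
            raise ValueError("jitter and noise SDs must be nonnegative")
        for idx, amp, prem in self.extrasystoles:
            if not 0 < amp <= 1:
                raise ValueError(f"extrasystole amplitude ratio {amp} not in (0, 1]")
            if not 0 < prem < 1:
                raise ValueError(f"prematurity ratio {prem} not in (0, 1)")
        for idx, mult, length in self.arrhythmia_episodes:
            if mult <= 0 or length < 1:
                raise ValueError("arrhythmia episodes need mult > 0, length >= 1")
        if self.baseline_wander is not None:
            freq, amp = self.baseline_wander
            if freq <= 0 or amp < 0:
                raise ValueError("baseline wander needs freq > 0, amplitude >= 0")


@dataclass
class SCRSimSpec:
    """Recipe for a synthetic labeled SCR record.

    ``responses`` lists ``(onset_s, amplitude_V, rise_s, decay_s)`` kernels;
    samples inside ``[onset, onset + rise + decay)`` carry the stress label,
    all others relax.
    """

    duration_s: float = 300.0
    fs: float = SCR_FS_HZ
    baseline_v: float = 0.68
    drift_v_per_min: float = 0.0
    responses: list = field(default_factory=list)
    noise_sd_v: float = 0.0
    quantize: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not 0 <= self.baseline_v <= SCR_ADC_VMAX_V:
            raise ValueError("baseline_v outside the ADC range")
        for onset, amp, rise, decay in self.responses:
            if onset < 0 or onset + rise + decay > self.duration_s:
                raise ValueError(
                    f"response at t={onset} s extends outside the record"
                )
            if rise <= 0 or decay <= 0:
                raise ValueError("rise_s and decay_s must be positive")


def _beat_schedule(spec: ECGSimSpec, rng: np.random.Generator):
    """Beat times, per-beat amplitude ratios and classes from the spec."""
    rr_nominal = 60.0 / spec.hr_bpm
    es_by_index = {int(e[0]): (float(e[1]), float(e[2]))
                   for e in spec.extrasystoles}
    rr_mult = {}
    for start, mult, length in spec.arrhythmia_episodes:
        for k in range(int(length)):
            rr_mult[int(start) + k] = float(mult)

    times: list[float] = []
    amps: list[float] = []
    classes: list[str] = []
    t = FIRST_BEAT_S
    i = 0
    while t < spec.duration_s - END_MARGIN_S:
        times.append(t)
        if i in es_by_index:
            # retime this beat as premature with a compensatory pause
            amp, prem = es_by_index[i]
            prev = times[-2] if len(times) > 1 else 0.0
            base_rr = times[-1] - prev if len(times) > 1 else rr_nominal
            times[-1] = prev + prem * base_rr
            t = prev + 2.0 * base_rr          # full compensation
            amps.append(amp)
            classes.append("extrasystole")
        else:
            rr = rr_nominal * rr_mult.get(i, 1.0)
            if spec.rr_jitter_sd_s:
                rr = max(rr + rng.normal(0.0, spec.rr_jitter_sd_s), 0.25)
            t = times[-1] + rr
            amps.append(1.0)
            classes.append("R")
        i += 1
    return (np.asarray(times), np.asarray(amps),
            np.asarray(classes, dtype=object))


def gen_ecg(spec: ECGSimSpec):
    """Generate a synthetic ECG with ground-truth beat annotations.

    Returns ``(record, truth_times, truth_classes)`` where ``truth_times``
    are the R-apex times in seconds and ``truth_classes`` the per-beat
    class ("R" or "extrasystole").  Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    beat_t, beat_amp, beat_cls = _beat_schedule(spec, rng)
    n = int(round(spec.duration_s * spec.fs))
    tt = np.arange(n) / spec.fs
    x = np.zeros(n)
    for bt, amp in zip(beat_t, beat_amp):
        for rel_amp, offset, width in ECG_TEMPLATE:
            sigma = width / 2.355          # FWHM -> Gaussian sigma
            mu = bt + offset
            lo = np.searchsorted(tt, mu - 5 * sigma)
            hi = np.searchsorted(tt, mu + 5 * sigma)
            seg = tt[lo:hi]
            x[lo:hi] += (spec.amplitude_mv * amp * rel_amp
                         * np.exp(-0.5 * ((seg - mu) / sigma) ** 2))
    if spec.baseline_wander is not None:
        freq, amp = spec.baseline_wander
        x += amp * np.sin(2 * np.pi * freq * tt)
    if spec.noise_sd_mv:
        x += rng.normal(0.0, spec.noise_sd_mv, n)
    if spec.quantize:
        x = np.clip(np.round(x / ECG_RESOLUTION_MV) * ECG_RESOLUTION_MV,
                    0.0, 50.0)
    record = ECGRecord(x, fs=spec.fs, raw=spec.quantize)
    return record, beat_t, beat_cls


def gen_scr(spec: SCRSimSpec) -> SCRRecord:
    """Generate a synthetic labeled SCR record.

    Baseline plus linear drift plus stimulus-locked response kernels
    (linear rise to the peak over ``rise_s``, exponential decay with time
    constant ``decay_s``) plus white noise, clipped to the ADC range.
    Samples inside a response span are labeled stress, the rest relax.
    Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    tt = np.arange(n) / spec.fs
    x = spec.baseline_v + spec.drift_v_per_min * tt / 60.0
    labels = np.full(n, "relax", dtype=object)
    for onset, amp, rise, decay in spec.responses:
        rel = tt - onset
        rising = (rel >= 0) & (rel < rise)
        decaying = rel >= rise
        x = x + np.where(rising, amp * rel / rise, 0.0)
        x = x + np.where(decaying, amp * np.exp(-(rel - rise) / decay), 0.0)
        labels[(rel >= 0) & (rel < rise + decay)] = "stress"
    if spec.noise_sd_v:
        x = x + rng.normal(0.0, spec.noise_sd_v, n)
    x = np.clip(x, 0.0, SCR_ADC_VMAX_V)
    if spec.quantize:
        x = np.clip(np.round(x / SCR_ADC_RESOLUTION_V) * SCR_ADC_RESOLUTION_V,
                    0.0, SCR_ADC_VMAX_V)
    return SCRRecord(x, fs=spec.fs, labels=labels)
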