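"""R-peak detection on single-lead ECG via the continuous wavelet transform.

The detector correlates the ECG with scaled copies of a Coiflet-5 mother
wavelet, squares the selected-scale coefficients into a nonnegative
detection series, and thresholds window-normalized local maxima: candidates
above 60% of the per-window reference are R waves, candidates between 30%
and 60% are provisional extrasystoles (premature beats often present reduced
QRS amplitude), and anything below 30% is discarded.  Squaring makes the
pipeline invariant to the overall sign of the lead, and normalizing each
five-second window makes detection invariant to amplitude scaling; the
band-pass character of the wavelet suppresses baseline wander and motion
artifacts.

The CWT is the integral ``C(a, b) = a^{-1/2} \\int x(t) \\psi*((t - b)/a) dt``
with scale ``a`` and shift ``b``; here time is measured in samples, so ``a``
is a dimensionless scale in sample units and the integral becomes a discrete
correlation against the sampled wavelet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import fftconvolve, find_peaks

from .signal_io import ECGRecord

__all__ = [
    "CWTCoefficients",
    "RPeakList",
    "UnsupportedWaveletError",
    "ShortInputError",
    "cwt",
    "transform_coefficients",
    "select_scale",
    "detect_r_peaks",
    "DEFAULT_WAVELET",
    "DEFAULT_SCALES",
    "R_CLASS",
    "ES_CLASS",
]

DEFAULT_WAVELET = "coif5"
#: Scale grid in sample units; at 250 Hz the effective wavelet width
#: (about 4 time units) then spans QRS-like durations of roughly 20-120 ms.
DEFAULT_SCALES = tuple(float(a) for a in range(2, 11))
DEFAULT_WINDOW_S = 5.0
R_THRESHOLD = 0.6
ES_THRESHOLD = 0.3
REFRACTORY_S = 0.2          # physiological minimum between beats
#: Candidate local maxima below this window-normalized height are ignored.
CANDIDATE_FLOOR = 0.05
#: Windows whose squared detection series has max/median below this are
#: treated as beat-free (noise floor); QRS-bearing windows are impulsive
#: and sit orders of magnitude above it.
MIN_CREST = 60.0
#: Windows are extended by this margin on each side for peak finding so
#: beats near window boundaries are not truncated.
WINDOW_MARGIN_S = 0.3

R_CLASS = "R"
ES_CLASS = "extrasystole"


class UnsupportedWaveletError(ValueError):
    """Raised when the requested mother wavelet is not available."""


class ShortInputError(ValueError):
    """Raised when the record is shorter than one analysis window."""


@dataclass
class CWTCoefficients:
    """CWT coefficient matrix ``C[a, b]`` on the signal's sample grid.

    ``a`` holds the scales (sample units), ``b`` the shift grid (sample
    indices) and ``C`` the ``(len(a), len(b))`` coefficient matrix under L2
    normalization (prefactor ``1/sqrt(a)``).
    """

    a: np.ndarray
    b: np.ndarray
    C: np.ndarray
    wavelet_name: str = DEFAULT_WAVELET
    fs: float = 250.0

    def row(self, scale: float) -> np.ndarray:
        match = np.flatnonzero(np.isclose(self.a, scale))
        if not len(match):
            raise KeyError(
                f"scale {scale} not computed; available: {list(self.a)}"
            )
        return self.C[match[0]]


@dataclass
class RPeakList:
    """Detected beats: occurrence times (s), normalized amplitude, class."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    norm_amp: np.ndarray = field(default_factory=lambda: np.empty(0))
    klass: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.norm_amp = np.asarray(self.norm_amp, dtype=float)
        self.klass = np.asarray(self.klass, dtype=object)
        if not (len(self.times) == len(self.norm_amp) == len(self.klass)):
            raise ValueError("times, norm_amp and klass must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.norm_amp) and (
            self.norm_amp.min() < 0 or self.norm_amp.max() > 1 + 1e-12
        ):
            raise ValueError("norm_amp must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Wavelet sampling
# ---------------------------------------------------------------------------

def _sampled_wavelet(name: str):
    """Return (x, psi, t_peak) for a discrete-family mother wavelet."""
    try:
        wav = pywt.Wavelet(name)
    except ValueError:
        supported = [
            n for fam in pywt.families(short=True)
            for n in pywt.wavelist(fam, kind="discrete")
        ]
        raise UnsupportedWaveletError(
            f"wavelet {name!r} is not supported; choose one of {supported}"
        ) from None
    _phi, psi, x = wav.wavefun(level=10)
    t_peak = float(x[np.argmax(psi ** 2)])
    return np.asarray(x), np.asarray(psi), t_peak


def cwt(
    ecg: ECGRecord,
    wavelet: str = DEFAULT_WAVELET,
    scales=DEFAULT_SCALES,
    *,
    pad: str = "none",
) -> CWTCoefficients:
    """Continuous wavelet transform of the ECG at the given scales.

    Evaluates ``C(a, b) = a^{-1/2} sum_n x[n] psi((n - b) / a)`` for every
    shift ``b`` on the sample grid, with the wavelet sampled from its
    cascade approximation.  Linear in the input; a zero signal maps to zero
    coefficients.

    With ``pad="none"`` (default) the sum runs over the available samples
    only, which is the literal discretization of the integral but leaves
    the trailing ``support * a`` shifts with a partially overlapped kernel;
    because the wavelet's zero mean no longer cancels there, the record
    edge can ring.  ``pad="reflect"`` mirrors the signal past the end
    before correlating, which the detection pipeline uses to keep the edge
    quiet.
    """
    if pad not in ("none", "reflect"):
        raise ValueError("pad must be 'none' or 'reflect'")
    scales = np.asarray(scales, dtype=float)
    if len(scales) == 0 or np.any(scales <= 0):
        raise ValueError("scales must be positive")
    x_grid, psi, _ = _sampled_wavelet(wavelet)
    sig = np.asarray(ecg.samples, dtype=float)
    n = len(sig)
    C = np.zeros((len(scales), n))
    support = x_grid[-1]
    for row, a in enumerate(scales):
        L = int(np.ceil(support * a))
        kernel = np.interp(np.arange(L + 1) / a, x_grid, psi)
        if n == 0:
            continue
        if pad == "reflect" and n > 1:
            ext = np.pad(sig, (0, L), mode="reflect")
        else:
            ext = sig
        # C[b] = sum_j ext[b + j] * kernel[j] / sqrt(a)
        full = fftconvolve(ext, kernel[::-1], mode="full")
        C[row] = full[L:L + n] / np.sqrt(a)
    return CWTCoefficients(a=scales, b=np.arange(n), C=C,
                           wavelet_name=wavelet, fs=ecg.fs)


def transform_coefficients(
    coeffs: CWTCoefficients, scale_select: float, *, strategy: str = "square"
) -> np.ndarray:
    """Turn the selected scale's coefficients into a detection series.

    The series is aligned to the sample grid (the wavelet's group delay of
    ``a * t_peak`` samples is compensated) and made nonnegative — squared by
    default, absolute value with ``strategy="abs"`` — so it is invariant to
    the overall sign of the ECG lead.
    """
    row = coeffs.row(scale_select)
    if strategy == "square":
        series = row ** 2
    elif strategy == "abs":
        series = np.abs(row)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    # Impulse at sample n responds at shift b = n - a * t_peak; roll right.
    _, _, t_peak = _sampled_wavelet(coeffs.wavelet_name)
    offset = int(round(scale_select * t_peak))
    aligned = np.zeros_like(series)
    if offset == 0:
        aligned[:] = series
    elif offset < len(series):
        aligned[offset:] = series[: len(series) - offset]
    return aligned


def select_scale(
    ecg: ECGRecord,
    wavelet: str = DEFAULT_WAVELET,
    scales=DEFAULT_SCALES,
    *,
    max_seconds: float = 30.0,
    strategy: str = "square",
) -> float:
    """Pick the analysis scale whose detection series is most impulsive.

    Scores each candidate scale by the peak-to-mean ratio of its detection
    series over the first ``max_seconds`` of the record and returns the
    arg-max (ties broken toward the smaller scale).  QRS complexes are the
    sharpest recurring feature of an ECG, so the matched scale maximizes
    this crest factor.
    """
    n = min(ecg.n, int(max_seconds * ecg.fs))
    head = ECGRecord(ecg.samples[:n], fs=ecg.fs)
    coeffs = cwt(head, wavelet, scales, pad="reflect")
    best_scale, best_score = float(coeffs.a[0]), -np.inf
    for a in coeffs.a:
        series = transform_coefficients(coeffs, a, strategy=strategy)
        mean = series.mean()
        score = series.max() / mean if mean > 0 else 0.0
        if score > best_score + 1e-12:
            best_scale, best_score = float(a), score
    return best_scale


# ---------------------------------------------------------------------------
# Windowed detection
# ---------------------------------------------------------------------------

def _window_bounds(n: int, fs: float, window_s: float):
    """Half-open, non-overlapping windows; final partial kept if >= 1 s."""
    size = int(round(window_s * fs))
    bounds = []
    start = 0
    while start < n:
        stop = min(start + size, n)
        if stop - start >= int(fs) or not bounds:
            bounds.append((start, stop))
        else:
            prev_start, _ = bounds[-1]
            bounds[-1] = (prev_start, stop)
        start += size
    return bounds


def detect_r_peaks(
    ecg: ECGRecord,
    *,
    wavelet: str = DEFAULT_WAVELET,
    window_s: float = DEFAULT_WINDOW_S,
    r_threshold: float = R_THRESHOLD,
    es_threshold: float = ES_THRESHOLD,
    scale: float | None = None,
    scales=DEFAULT_SCALES,
    threshold_mode: str = "maxima_mean",
    strategy: str = "square",
    refractory_s: float = REFRACTORY_S,
    min_crest: float = MIN_CREST,
    allow_short: bool = False,
) -> RPeakList:
    """Detect R peaks (and provisional extrasystoles) in an ECG record.

    The record is processed in non-overlapping ``window_s`` windows of the
    detection series.  In each window the series is normalized to maximum 1
    and local maxima separated by at least ``refractory_s`` are collected as
    candidates.  With ``threshold_mode="maxima_mean"`` (default) the
    per-window reference is the mean candidate amplitude, so thresholds act
    at beat level; with ``"window_max"`` the reference is the window maximum
    (1 after normalization).  Candidates above ``r_threshold`` times the
    reference are R waves, candidates in the ``(es_threshold, r_threshold]``
    band are provisional extrasystoles, the rest are dropped.  Windows whose
    squared series is not impulsive (max/median below ``min_crest``) are
    treated as beat-free.

    Detection times are invariant to positive amplitude scaling of the
    input.  Records shorter than one window raise :class:`ShortInputError`
    unless ``allow_short`` is set.
    """
    if threshold_mode not in ("maxima_mean", "window_max"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    fs = ecg.fs
    n = ecg.n
    if n < int(window_s * fs):
        if not allow_short:
            raise ShortInputError(
                f"record of {n / fs:.3g} s is shorter than one "
                f"{window_s:.3g} s window; pass allow_short=True to process "
                "a single truncated window"
            )
        if n < 2:
            return RPeakList()
    if scale is None:
        scale = select_scale(ecg, wavelet, scales, strategy=strategy)
    coeffs = cwt(ecg, wavelet, [scale], pad="reflect")
    series = transform_coefficients(coeffs, scale, strategy=strategy)

    margin = int(WINDOW_MARGIN_S * fs)
    distance = max(int(refractory_s * fs), 1)
    times: list[float] = []
    amps: list[float] = []
    classes: list[str] = []
    for start, stop in _window_bounds(n, fs, window_s):
        lo = max(start - margin, 0)
        hi = min(stop + margin, n)
        win = series[lo:hi]
        peak_val = win.max()
        if peak_val <= 0:
            continue
        crest = peak_val / max(np.median(win), peak_val * 1e-15)
        if strategy == "abs":
            crest = crest ** 2   # guard is calibrated on the squared series
        if crest < min_crest:
            continue  # noise floor: no impulsive beats in this window
        norm = win / peak_val
        idx, _ = find_peaks(norm, distance=distance, height=CANDIDATE_FLOOR)
        if not len(idx):
            continue
        # Report amplitudes on the |C| scale so the 30%/60% bands act on
        # amplitude ratios (a squared series would halve them in dB terms).
        amp = np.sqrt(norm[idx]) if strategy == "square" else norm[idx]
        ref = amp.mean() if threshold_mode == "maxima_mean" else 1.0
        for i, a_i in zip(idx, amp):
            t = (lo + i) / fs
            if not (start / fs <= t < stop / fs):
                continue  # belongs to the neighbouring window
            ratio = a_i / ref
            if ratio > r_threshold:
                cls = R_CLASS
            elif ratio > es_threshold:
                cls = ES_CLASS
            else:
                continue
            times.append(t)
            amps.append(min(float(a_i), 1.0))
            classes.append(cls)

    order = np.argsort(times)
    t_arr = np.asarray(times)[order]
    a_arr = np.asarray(amps)[order]
    c_arr = np.asarray(classes, dtype=object)[order]
    # Enforce the refractory period across window seams.
    keep = np.ones(len(t_arr), dtype=bool)
    last_t = -np.inf
    for i, t in enumerate(t_arr):
        if t - last_t < refractory_s:
            keep[i] = False
        else:
            last_t = t
    return RPeakList(times=t_arr[keep], norm_amp=a_arr[keep], klass=c_arr[keep])
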