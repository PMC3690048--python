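"""Heart-rate-variability series: RR intervals, resampling and statistics.

The RR-interval series (time between consecutive R peaks) is inherently
non-uniform: one value per beat, anchored at the beat time that ends the
interval.  For plotting and joint analysis with other channels the series
is resampled with shape-preserving piecewise-cubic Hermite interpolation
(PCHIP), which passes through every knot and never overshoots the local
data range — a monotone ramp stays monotone, unlike a natural cubic spline.

Protocol-window statistics (mean and sample standard deviation of the raw
RR intervals) summarize variability per experiment phase; under a cognitive
stressor such as a color-word interference task the RR standard deviation
typically drops relative to rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "RRSeries",
    "EmptyWindowError",
    "rr_from_beats",
    "interpolate_hrv",
    "rr_stats",
]

DEFAULT_RESAMPLE_FS = 4.0


class EmptyWindowError(ValueError):
    """The requested statistics window contains no RR intervals."""


@dataclass
class RRSeries:
    """Inter-beat intervals ``rr`` anchored at interval-end times ``anchor_t``."""

    anchor_t: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.anchor_t = np.asarray(self.anchor_t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if len(self.anchor_t) != len(self.rr):
            raise ValueError("anchor_t and rr must align")
        if len(self.anchor_t) > 1 and np.any(np.diff(self.anchor_t) <= 0):
            raise ValueError("anchor_t must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("rr intervals must be positive")

    def __len__(self) -> int:
        return len(self.rr)


def rr_from_beats(t) -> RRSeries:
    """Build the RR series from a beat-time train.

    Each interval is anchored at its ending beat; ``sum(rr)`` equals the
    span from the first to the last beat exactly.  Fewer than two beats
    yield an empty series.
    """
    t = np.asarray(t, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("beat times must be strictly increasing")
    if len(t) < 2:
        return RRSeries(np.empty(0), np.empty(0))
    return RRSeries(anchor_t=t[1:], rr=np.diff(t))


def interpolate_hrv(series: RRSeries, out_fs: float = DEFAULT_RESAMPLE_FS):
    """Resample the RR series uniformly with shape-preserving cubic Hermite.

    Returns ``(t_uniform, rr_uniform)`` sampled at ``out_fs`` over
    ``[anchor_t[0], anchor_t[-1]]``.  The interpolant reproduces every knot
    exactly and stays within ``[min(rr), max(rr)]`` on monotone segments.
    """
    if out_fs <= 0:
        raise ValueError("out_fs must be positive")
    if len(series) < 2:
        raise ValueError("interpolation needs at least 2 RR intervals")
    interp = PchipInterpolator(series.anchor_t, series.rr)
    t0, t1 = series.anchor_t[0], series.anchor_t[-1]
    n = int(np.floor((t1 - t0) * out_fs)) + 1
    t_uniform = t0 + np.arange(n) / out_fs
    return t_uniform, interp(t_uniform)


def rr_stats(series: RRSeries, window=None, *, units: str = "s"):
    """Mean and sample standard deviation of raw RR intervals in a window.

    ``window`` is a ``(start_s, end_s)`` pair selecting intervals by their
    anchor time, bounds normalized so order does not matter; ``None`` uses
    the whole series.  ``units="bpm"`` converts each interval to
    instantaneous heart rate (60/rr) before computing the statistics.  The
    standard deviation uses the n-1 denominator (0.0 for a single
    interval).
    """
    if units not in ("s", "bpm"):
        raise ValueError("units must be 's' or 'bpm'")
    if window is None:
        sel = series.rr
    else:
        lo, hi = sorted(float(w) for w in window)
        mask = (series.anchor_t >= lo) & (series.anchor_t <= hi)
        sel = series.rr[mask]
    if len(sel) == 0:
        raise EmptyWindowError("no RR intervals inside the requested window")
    vals = 60.0 / sel if units == "bpm" else sel
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd
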