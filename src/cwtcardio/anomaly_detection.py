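"""Rule-based beat classification: extrasystoles and arrhythmic RR changes.

Two printed ratio rules operate on the beat-time sequence ``t(0..n-1)``:

* extrasystole timing rule — beat ``i`` is premature when the interval that
  precedes it, stretched by 2.2, still fits inside the interval that
  follows it: ``(t(i) - t(i-1)) * 2.2 < (t(i+1) - t(i))``.  A premature
  beat shortens its preceding RR interval and is followed by a
  compensatory pause, producing exactly this signature.
* arrhythmia rule — the interval ending at beat ``i`` differs from its
  predecessor by 30% or more in either direction:
  ``RR(i) >= 1.3 * RR(i-1)`` or ``1.3 * RR(i) <= RR(i-1)``.

Both rules compare interval ratios only, so classifications are invariant
to shifting all beat times by a constant and to rescaling time by any
positive factor.

Amplitude information enters through the detector's normalized amplitudes:
beats in the (0.3, 0.6] band are extrasystoles outright; higher-amplitude
beats can still be re-classified as extrasystoles by the timing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qrs_detection import ES_CLASS, ES_THRESHOLD, R_CLASS, R_THRESHOLD, RPeakList

__all__ = [
    "AnomalyReport",
    "extrasystole_timing_rule",
    "classify_beats",
    "detect_arrhythmia",
    "merge_episodes",
    "ES_TIMING_FACTOR",
    "ARRHYTHMIA_RATIO",
]

ES_TIMING_FACTOR = 2.2
ARRHYTHMIA_RATIO = 1.3


@dataclass
class AnomalyReport:
    """Beat-level anomaly classification.

    ``extrasystole_indices`` and ``arrhythmia_indices`` are 0-based beat
    indices; an arrhythmia flag at ``i`` refers to the RR interval ending at
    ``t(i)`` (so flags require ``i >= 2``).  ``rr`` holds the derived RR
    intervals, ``rr[j] = t(j+1) - t(j)``.  ``episodes`` merges contiguous
    arrhythmia flags into ``(first_index, last_index)`` spans.
    """

    classes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    extrasystole_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    arrhythmia_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    rr: np.ndarray = field(default_factory=lambda: np.empty(0))
    episodes: list[tuple[int, int]] = field(default_factory=list)


def _as_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError("beat times must be one-dimensional")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return t


def extrasystole_timing_rule(t, i: int, factor: float = ES_TIMING_FACTOR) -> bool:
    """Premature-beat timing test at beat ``i`` (0-based).

    True iff ``(t[i] - t[i-1]) * factor < t[i+1] - t[i]`` (strict).  ``i``
    must be an interior index: ``1 <= i <= n - 2``.
    """
    t = _as_times(t)
    if not 1 <= i <= len(t) - 2:
        raise IndexError(
            f"timing rule needs an interior beat; got i={i} for n={len(t)}"
        )
    return bool((t[i] - t[i - 1]) * factor < (t[i + 1] - t[i]))


def classify_beats(peaks: RPeakList, factor: float = ES_TIMING_FACTOR,
                   *, r_threshold: float = R_THRESHOLD,
                   es_threshold: float = ES_THRESHOLD) -> AnomalyReport:
    """Split detected beats into R waves and extrasystoles.

    Beats whose normalized amplitude lies in ``(es_threshold, r_threshold]``
    are extrasystoles by the amplitude band.  Beats above the band are
    checked with the timing rule — an extrasystole can exceed 60% amplitude,
    in which case its premature timing betrays it.  First and last beats
    cannot be tested by the timing rule and keep their amplitude-band class.
    """
    t = _as_times(peaks.times)
    n = len(t)
    classes = np.empty(n, dtype=object)
    for i in range(n):
        amp_es = es_threshold < peaks.norm_amp[i] <= r_threshold
        timing_es = (
            peaks.norm_amp[i] > r_threshold
            and 1 <= i <= n - 2
            and extrasystole_timing_rule(t, i, factor)
        )
        classes[i] = ES_CLASS if (amp_es or timing_es) else R_CLASS
    es_idx = np.flatnonzero(classes == ES_CLASS)
    arr_idx = detect_arrhythmia(t)
    return AnomalyReport(
        classes=classes,
        extrasystole_indices=es_idx,
        arrhythmia_indices=arr_idx,
        rr=np.diff(t),
        episodes=merge_episodes(arr_idx),
    )


def detect_arrhythmia(t, ratio: float = ARRHYTHMIA_RATIO) -> np.ndarray:
    """Flag beats ending an RR interval that jumps by >= 30% either way.

    Beat ``i`` (0-based, ``i >= 2``) is flagged iff
    ``RR(i) >= ratio * RR(i-1)`` or ``ratio * RR(i) <= RR(i-1)`` with
    ``RR(i) = t[i] - t[i-1]``.  Fewer than 3 beats yield an empty result.
    """
    t = _as_times(t)
    if len(t) < 3:
        return np.empty(0, dtype=int)
    rr = np.diff(t)
    cur, prev = rr[1:], rr[:-1]
    flagged = (cur >= ratio * prev) | (ratio * cur <= prev)
    return np.flatnonzero(flagged) + 2


def merge_episodes(indices) -> list[tuple[int, int]]:
    """Merge contiguous flagged beat indices into (first, last) spans."""
    indices = np.asarray(indices, dtype=int)
    if not len(indices):
        return []
    episodes = []
    start = prev = int(indices[0])
    for i in indices[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
        else:
            episodes.append((start, prev))
            start = prev = i
    episodes.append((start, prev))
    return episodes
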