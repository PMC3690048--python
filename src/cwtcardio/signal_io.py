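"""Readers, writers and frame reassembly for wearable ECG / SCR streams.

The chest-strap device this toolkit targets emits three frame kinds over its
radio link: ECG waveform frames (one sample every 4 ms, 63 samples per
252 ms frame), breathing-waveform frames (one sample every 56 ms, 18 samples
per 1.008 s frame) and summary frames carrying scalar vitals, with the heart
rate encoded in payload bytes 12-13.  This module reassembles such frame
streams into uniformly sampled records and round-trips ECG/SCR series and
beat annotations through plain CSV/TSV files.

Time bases are implicit (0-based sample index divided by the sampling rate,
in seconds); explicit timestamp columns are validated, never resampled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ECG_FS_HZ",
    "ECG_RESOLUTION_MV",
    "ECG_RANGE_MV",
    "ECG_SAMPLES_PER_FRAME",
    "BREATHING_SAMPLES_PER_FRAME",
    "SCR_FS_HZ",
    "SCR_ADC_RESOLUTION_V",
    "SCR_ADC_VMAX_V",
    "ECGRecord",
    "SCRRecord",
    "FrameStream",
    "ParseError",
    "FormatError",
    "FrameError",
    "read_ecg_csv",
    "write_ecg_csv",
    "read_scr_csv",
    "write_scr_csv",
    "reassemble_frames",
    "write_annotations",
    "read_annotations",
]

# Device constants: ECG sampled every 4 ms on a 0.013405 mV grid spanning
# 0-50 mV; frames carry 252 ms of ECG or 1.008 s of breathing waveform.
ECG_FS_HZ = 250.0
ECG_RESOLUTION_MV = 0.013405
ECG_RANGE_MV = (0.0, 50.0)
ECG_SAMPLES_PER_FRAME = 63          # 252 ms / 4 ms
BREATHING_SAMPLES_PER_FRAME = 18    # 1.008 s / 56 ms
BREATHING_FS_HZ = 1.0 / 0.056

SCR_FS_HZ = 4.0
SCR_ADC_RESOLUTION_V = 0.573e-3
SCR_ADC_VMAX_V = 2.35

HR_BYTE_OFFSET = 12                 # summary payload bytes 12-13 hold HR
SUMMARY_MIN_PAYLOAD = HR_BYTE_OFFSET + 2

SCR_LABELS = ("stress", "relax", "unlabeled")


class ParseError(ValueError):
    """A CSV row could not be parsed as numeric data."""


class FormatError(ValueError):
    """A file's structure contradicts the declared format."""


class FrameError(ValueError):
    """A frame payload is inconsistent with its declared kind."""


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead ECG.

    Parameters
    ----------
    samples : array of float
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz (device default 250).
    start_time : float
        Offset of the first sample in seconds.
    subject_id : str or None
        Opaque subject label.
    raw : bool
        When True the samples are asserted to lie on the device ADC grid
        (integer multiples of 0.013405 mV within 0-50 mV).
    """

    samples: np.ndarray
    fs: float = ECG_FS_HZ
    start_time: float = 0.0
    subject_id: str | None = None
    raw: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.raw and len(self.samples):
            lo, hi = ECG_RANGE_MV
            if self.samples.min() < lo - 1e-9 or self.samples.max() > hi + 1e-9:
                raise ValueError("raw ECG samples outside the device range")
            ticks = self.samples / ECG_RESOLUTION_MV
            if np.max(np.abs(ticks - np.round(ticks))) * ECG_RESOLUTION_MV > 1e-9:
                raise ValueError("raw ECG samples off the device ADC grid")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Span from the first to the last sample, in seconds."""
        return max(self.n - 1, 0) / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ECGRecord):
            return NotImplemented
        return (
            np.array_equal(self.samples, other.samples)
            and self.fs == other.fs
            and self.start_time == other.start_time
            and self.subject_id == other.subject_id
        )


@dataclass
class SCRRecord:
    """Skin-conductance-response voltage series at 4 Hz.

    ``labels`` (optional) holds a per-sample protocol class drawn from
    {"stress", "relax", "unlabeled"}.
    """

    samples: np.ndarray
    fs: float = SCR_FS_HZ
    labels: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.samples) and (
            self.samples.min() < -1e-12 or self.samples.max() > SCR_ADC_VMAX_V + 1e-12
        ):
            raise ValueError(
                f"SCR samples must lie in [0, {SCR_ADC_VMAX_V}] V"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.samples):
                raise ValueError("labels must match samples in length")
            bad = set(self.labels) - set(SCR_LABELS)
            if bad:
                raise ValueError(f"unknown SCR labels: {sorted(map(str, bad))}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SCRRecord):
            return NotImplemented
        same_labels = (self.labels is None) == (other.labels is None) and (
            self.labels is None or np.array_equal(self.labels, other.labels)
        )
        return (
            np.array_equal(self.samples, other.samples)
            and self.fs == other.fs
            and same_labels
        )


FRAME_KINDS = ("ecg", "breathing", "summary")


@dataclass
class FrameStream:
    """Ordered list of ``(kind, payload)`` frames from the device link."""

    frames: list[tuple[str, bytes]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for idx, (kind, payload) in enumerate(self.frames):
            if kind not in FRAME_KINDS:
                raise FrameError(f"frame {idx}: unknown kind {kind!r}")
            if not isinstance(payload, (bytes, bytearray)):
                raise FrameError(f"frame {idx}: payload must be bytes")


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def _read_numeric_csv(path, max_cols: int) -> pd.DataFrame:
    """Read a comma-separated numeric table, tolerating one header row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    header_offset = 0
    first = df.iloc[0]
    try:
        first.astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
        header_offset = 1
    if df.shape[1] > max_cols:
        raise FormatError(
            f"{path.name}: expected at most {max_cols} columns, got {df.shape[1]}"
        )
    out = pd.DataFrame()
    for col in df.columns:
        try:
            out[col] = df[col].astype(float)
        except (TypeError, ValueError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value on line {bad + 1 + header_offset}"
            ) from None
    return out

def _validate_timestamps(t: np.ndarray, fs: float, name: str) -> float:
    """Check explicit timestamps against the declared rate; return start."""
    if len(t) < 2:
        return float(t[0]) if len(t) else 0.0
    dt = np.diff(t)
    expected = 1.0 / fs
    if np.max(np.abs(dt - expected)) > 0.01 * expected + 1e-9:
        raise FormatError(
            f"{name}: timestamps are not uniform at fs={fs} Hz "
            f"(max spacing deviation {np.max(np.abs(dt - expected)):.3g} s)"
        )
    return float(t[0])

def read_ecg_csv(path, fs: float = ECG_FS_HZ, *, subject_id: str | None = None,
                 raw: bool = False) -> ECGRecord:
    """Read an ECG record from CSV.

    Accepts one numeric column (mV) or two columns (time in s, mV).  With two
    columns the timestamps must be uniform at ``fs`` within 1%; they set the
    record's ``start_time`` and are otherwise discarded.
    """
    df = _read_numeric_csv(path, max_cols=2)
    if df.empty:
        return ECGRecord(np.empty(0), fs=fs, subject_id=subject_id, raw=raw)
    if df.shape[1] == 2:
        start = _validate_timestamps(df.iloc[:, 0].to_numpy(), fs, Path(path).name)
        samples = df.iloc[:, 1].to_numpy()
    else:
        start = 0.0
        samples = df.iloc[:, 0].to_numpy()
    return ECGRecord(samples, fs=fs, start_time=start, subject_id=subject_id,
                     raw=raw)

def write_ecg_csv(record: ECGRecord, path, *, include_time: bool = False) -> None:
    """Write an ECG record as CSV with a header row (mV, full precision)."""
    cols = {}
    if include_time:
        cols["time_s"] = record.time
    cols["ecg_mV"] = record.samples
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")

def read_scr_csv(path, fs: float = SCR_FS_HZ,
                 *, subject_id: str | None = None) -> SCRRecord:
    """Read an SCR record from CSV: one voltage column, optional labels.

    The label column, when present, must be the last column and contain
    values in {stress, relax, unlabeled}; it is detected by being
    non-numeric.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return SCRRecord(np.empty(0), fs=fs, subject_id=subject_id)
    try:
        df.iloc[0].iloc[0] and float(df.iloc[0].iloc[0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    labels = None
    last = df.iloc[:, -1]
    if df.shape[1] > 1 and pd.to_numeric(last, errors="coerce").isna().all():
        labels = last.to_numpy(dtype=object)
        df = df.iloc[:, :-1]
    buf = io.StringIO(df.to_csv(index=False, header=False))
    num = _read_numeric_csv_buffer(buf, path.name, max_cols=2)
    if num.shape[1] == 2:
        _validate_timestamps(num.iloc[:, 0].to_numpy(), fs, path.name)
        samples = num.iloc[:, 1].to_numpy()
    else:
        samples = num.iloc[:, 0].to_numpy()
    return SCRRecord(samples, fs=fs, labels=labels, subject_id=subject_id)

def _read_numeric_csv_buffer(buf, name: str, max_cols: int) -> pd.DataFrame:
    df = pd.read_csv(buf, header=None, dtype=str, skip_blank_lines=True)
    out = pd.DataFrame()
    if df.shape[1] > max_cols:
        raise FormatError(f"{name}: expected at most {max_cols} numeric columns")
    for col in df.columns:
        try:
            # str -> float via numpy: correctly rounded, unlike to_numeric
            out[col] = df[col].astype(float)
        except (TypeError, ValueError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(
                f"{name}: non-numeric value on line {bad + 1}"
            ) from None
    return out

def write_scr_csv(record: SCRRecord, path) -> None:
    cols = {"scr_V": record.samples}
    if record.labels is not None:
        cols["label"] = record.labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Frame reassembly
# ---------------------------------------------------------------------------

def _decode_u16(payload: bytes, n: int, idx: int, byte_order: str) -> np.ndarray:
    dtype = "<u2" if byte_order == "little" else ">u2"
    if len(payload) != 2 * n:
        raise FrameError(
            f"frame {idx}: expected {2 * n} payload bytes, got {len(payload)}"
        )
    return np.frombuffer(bytes(payload), dtype=dtype).astype(float)

def reassemble_frames(
    stream: FrameStream, *, hr_byte_order: str = "little"
) -> tuple[ECGRecord, np.ndarray, np.ndarray]:
    """Reassemble a device frame stream into uniform sample series.

    ECG frames are decoded as 63 unsigned 16-bit ADC counts (little-endian)
    scaled by the 0.013405 mV ADC step and concatenated on the 4 ms grid;
    breathing frames as 18 counts on the 56 ms grid.  Summary frames yield
    one heart-rate value each, read from payload bytes 12-13 as an unsigned
    16-bit integer whose byte order is ``hr_byte_order`` ("little" default,
    flip with "big").

    Returns ``(ecg_record, breathing_samples, heart_rates)``.
    """
    if hr_byte_order not in ("little", "big"):
        raise ValueError("hr_byte_order must be 'little' or 'big'")
    ecg_chunks: list[np.ndarray] = []
    breathing_chunks: list[np.ndarray] = []
    heart_rates: list[float] = []
    for idx, (kind, payload) in enumerate(stream.frames):
        if kind == "ecg":
            counts = _decode_u16(payload, ECG_SAMPLES_PER_FRAME, idx, "little")
            ecg_chunks.append(counts * ECG_RESOLUTION_MV)
        elif kind == "breathing":
            breathing_chunks.append(
                _decode_u16(payload, BREATHING_SAMPLES_PER_FRAME, idx, "little")
            )
        else:
            if len(payload) < SUMMARY_MIN_PAYLOAD:
                raise FrameError(
                    f"frame {idx}: summary payload shorter than "
                    f"{SUMMARY_MIN_PAYLOAD} bytes"
                )
            pair = bytes(payload[HR_BYTE_OFFSET:HR_BYTE_OFFSET + 2])
            heart_rates.append(float(int.from_bytes(pair, hr_byte_order)))
    ecg = np.concatenate(ecg_chunks) if ecg_chunks else np.empty(0)
    breathing = np.concatenate(breathing_chunks) if breathing_chunks else np.empty(0)
    return (
        ECGRecord(ecg, fs=ECG_FS_HZ, raw=bool(ecg_chunks)),
        breathing,
        np.asarray(heart_rates),
    )


# ---------------------------------------------------------------------------
# Beat annotations (TSV)
# ---------------------------------------------------------------------------

ANNOTATION_HEADER = "time_s\tclass\tnorm_amp"

def write_annotations(peaks, path) -> None:
    """Write a beat list as TSV ``(time_s, class, normalized amplitude)``.

    ``peaks`` is any object with ``times``, ``klass`` and ``norm_amp``
    sequences (see :class:`cwtcardio.qrs_detection.RPeakList`).  Times must
    be sorted strictly ascending.
    """
    times = np.asarray(peaks.times, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("peak times must be strictly increasing")
    with open(path, "w") as fh:
        fh.write(ANNOTATION_HEADER + "\n")
        for t, k, a in zip(times, peaks.klass, peaks.norm_amp):
            fh.write(f"{t:.17g}\t{k}\t{a:.17g}\n")

def read_annotations(path):
    """Read a TSV beat list written by :func:`write_annotations`."""
    from .qrs_detection import RPeakList

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ANNOTATION_HEADER.split("\t"):
        raise FormatError(f"{Path(path).name}: unexpected annotation columns")
    return RPeakList(
        times=df["time_s"].to_numpy(dtype=float),
        norm_amp=df["norm_amp"].to_numpy(dtype=float),
        klass=df["class"].to_numpy(dtype=object),
    )
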