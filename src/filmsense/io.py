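"""Reading and writing physiological recordings.

Two interchange formats are supported:

* **CSV** — the package's native dialect: UTF-8, metadata as ``# key: value``
  comment lines (``fs_hz``, ``modality``, ``subject_id``, ``condition``,
  ``units``), then a ``time_s,value`` header and one sample per row.
  Round-trips are lossless (values are written with 17 significant digits).
* **EDF** — European Data Format, one signal per file, for archival use.
  EDF stores samples as 16-bit integers scaled to a declared physical range,
  so the round-trip is lossy by at most one quantization step.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("ECG", "EDA", "RF")
CONDITIONS = ("caffeine", "placebo")

DEFAULT_UNITS = {"ECG": "mV", "EDA": "uS", "RF": "au"}


class FormatError(ValueError):
    """A recording file violates the expected dialect."""


@dataclass
class SignalRecord:
    """One modality's sample stream for one subject and condition.

    Parameters
    ----------
    samples
        Amplitude array (mV for ECG, microsiemens for EDA, arbitrary units
        for the respiration band).
    fs
        Sampling rate in Hz.
    modality
        One of ``ECG``, ``EDA``, ``RF``.
    subject_id
        Subject identifier.
    condition
        ``caffeine`` or ``placebo``.
    units
        Physical unit label; defaults to the modality's conventional unit.
    """

    samples: np.ndarray
    fs: float
    modality: str
    subject_id: str
    condition: str
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")
        if not self.units:
            self.units = DEFAULT_UNITS[self.modality]

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalRecord":
        """Copy of this record carrying new sample data."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("fs_hz", "modality", "subject_id", "condition", "units")


def write_recording(record: SignalRecord, path: str | Path, format: str = "csv") -> Path:
    """Write a record to ``path`` in the requested format.

    CSV is lossless; EDF quantizes to 16 bits over the sample range.
    """
    path = Path(path)
    if format == "csv":
        _write_csv(record, path)
    elif format == "edf":
        _write_edf(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> SignalRecord:
    """Read a record written by :func:`write_recording`.

    The format is inferred from the suffix when not given. The loader
    validates metadata and rejects NaN samples and time columns inconsistent
    with the declared sampling rate (more than half a sample period off).
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _write_csv(record: SignalRecord, path: Path) -> None:
    t = np.arange(record.n_samples) / record.fs
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# fs_hz: {record.fs!r}\n")
        fh.write(f"# modality: {record.modality}\n")
        fh.write(f"# subject_id: {record.subject_id}\n")
        fh.write(f"# condition: {record.condition}\n")
        fh.write(f"# units: {record.units}\n")
        fh.write("time_s,value\n")
        for ti, vi in zip(t, record.samples):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


def _read_csv(path: Path) -> SignalRecord:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing header metadata {missing}")
    try:
        fs = float(meta["fs_hz"])
    except ValueError as exc:
        raise FormatError(f"{path}: fs_hz is not numeric: {meta['fs_hz']!r}") from exc

    frame = pd.read_csv(path, skiprows=n_meta, float_precision="round_trip")
    if "value" not in frame.columns:
        raise FormatError(f"{path}: missing 'value' column")
    values = frame["value"].to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        raise FormatError(f"{path}: NaN in 'value' column")
    if "time_s" in frame.columns:
        t = frame["time_s"].to_numpy(dtype=np.float64)
        if t.size > 1:
            if np.any(np.diff(t) <= 0):
                raise FormatError(f"{path}: time_s column is not strictly increasing")
            expected = np.arange(t.size) / fs + t[0]
            if np.max(np.abs(t - expected)) > 0.5 / fs:
                raise FormatError(
                    f"{path}: time_s column inconsistent with fs_hz={fs} "
                    "(deviates by more than half a sample period)"
                )
    return SignalRecord(
        samples=values,
        fs=fs,
        modality=meta["modality"],
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        units=meta["units"],
    )


# ---------------------------------------------------------------------------
# Minimal EDF (one signal per file, one data record holding all samples)
# ---------------------------------------------------------------------------
# EDF header: 256 bytes global + 256 bytes per signal, ASCII fields.
# Samples: little-endian int16 mapped linearly from the declared physical
# range onto [-32768, 32767]. Quantization step = range / 65535.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def _write_edf(record: SignalRecord, path: Path) -> None:
    x = record.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:  # constant signal: widen range so the scale is nonzero
        hi = lo + 1.0
    n = x.size
    duration = n / record.fs

    scale = (hi - lo) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((x - lo) / scale) + _EDF_DIG_MIN
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    # local recording field carries our metadata so reads restore it
    recording_id = f"{record.subject_id} {record.modality} {record.condition} fs={record.fs!r}"
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(record.subject_id[:80], 80),
            _ascii(recording_id[:80], 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 + 256, 8),  # header bytes
            _ascii("", 44),
            _ascii(1, 8),  # number of data records
            _ascii(f"{duration:.8g}"[:8], 8),
            _ascii(1, 4),  # number of signals
            # per-signal fields
            _ascii(record.modality, 16),
            _ascii("synthetic", 80),
            _ascii(record.units[:8], 8),
            _ascii(f"{lo:.8g}"[:8], 8),
            _ascii(f"{hi:.8g}"[:8], 8),
            _ascii(_EDF_DIG_MIN, 8),
            _ascii(_EDF_DIG_MAX, 8),
            _ascii("", 80),
            _ascii(n, 8),
            _ascii("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> SignalRecord:
    with open(path, "rb") as fh:
        head = fh.read(512)
        if len(head) < 512:
            raise FormatError(f"{path}: truncated EDF header")
        recording_id = head[88:168].decode("ascii").strip()
        n_signals = int(head[252:256])
        if n_signals != 1:
            raise FormatError(f"{path}: expected exactly one EDF signal, got {n_signals}")
        label = head[256:272].decode("ascii").strip()
        units = head[272 + 80 : 272 + 88].decode("ascii").strip()
        phys_min = float(head[360:368])
        phys_max = float(head[368:376])
        dig_min = int(head[376:384])
        dig_max = int(head[384:392])
        n = int(head[472:480])
        raw = np.frombuffer(fh.read(2 * n), dtype="<i2")
    if raw.size != n:
        raise FormatError(f"{path}: expected {n} samples, found {raw.size}")

    parts = recording_id.split()
    meta: dict[str, str] = {}
    if len(parts) >= 4 and parts[-1].startswith("fs="):
        meta = {
            "subject_id": " ".join(parts[:-3]),
            "modality": parts[-3],
            "condition": parts[-2],
            "fs": parts[-1][3:],
        }
    if not meta:
        raise FormatError(f"{path}: EDF recording field lacks filmsense metadata")

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    samples = (raw.astype(np.float64) - dig_min) * scale + phys_min
    return SignalRecord(
        samples=samples,
        fs=float(meta["fs"]),
        modality=meta["modality"] or label,
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        units=units,
    )


def edf_quantization_step(record: SignalRecord) -> float:
    """The worst-case EDF round-trip error for this record's amplitude range."""
    lo, hi = float(np.min(record.samples)), float(np.max(record.samples))
    if hi <= lo:
        hi = lo + 1.0
    return (hi - lo) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
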