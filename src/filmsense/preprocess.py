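"""Per-modality FIR filtering and amplitude normalization.

The analysis chain filters each raw signal with a linear-phase FIR filter
(low-pass 1 Hz for electrodermal activity, low-pass 3 Hz for respiration,
band-pass 1–30 Hz for ECG), then rescales the amplitude and removes the mean.

Filter design is windowed-sinc (Hamming) with a default length of
``4 * fs / lowest_cutoff`` taps (capped at 8191), which puts the half
amplitude (−6 dB) point at each cutoff and gives > 50 dB stopband
attenuation. Filtering is zero-phase by default — one forward and one
backward pass over a reflection-padded signal — so segment boundaries and
peak positions are not shifted by group delay.

Amplitude normalization has two modes. ``unit-energy`` (the default)
divides by the root total energy, x ← x / sqrt(Σ x²), so every record has
total energy 1 and downstream window energies are comparable across
subjects and modalities. ``literal`` divides by the total energy itself,
x ← x / Σ x²; this variant is kept because it is sometimes written that
way, but it is not scale-invariant (doubling the input halves the output)
and is therefore not the default. In both modes the sample mean is
subtracted after the rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import SignalRecord

MAX_FIR_TAPS = 8191


class FilterDesignError(ValueError):
    """Invalid filter specification for the given sampling rate."""


class NormalizationError(ValueError):
    """Amplitude normalization is undefined (zero-energy signal)."""


@dataclass(frozen=True)
class FilterSpec:
    """A per-modality FIR filter specification.

    ``cutoffs`` holds one edge for a low-pass and (low, high) for a
    band-pass, in Hz. ``order`` is the number of taps; ``None`` applies the
    default rule ``4 * fs / lowest_cutoff`` (odd, capped at 8191).
    """

    modality: str
    kind: str  # "low-pass" | "band-pass"
    cutoffs: tuple[float, ...]
    order: int | None = None
    phase_mode: str = "zero-phase"  # or "single-pass"

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "band-pass"):
            raise FilterDesignError(f"unknown filter kind {self.kind!r}")
        n_expected = 1 if self.kind == "low-pass" else 2
        if len(self.cutoffs) != n_expected:
            raise FilterDesignError(
                f"{self.kind} filter needs {n_expected} cutoff(s), got {self.cutoffs}"
            )
        if any(c <= 0 for c in self.cutoffs) or list(self.cutoffs) != sorted(self.cutoffs):
            raise FilterDesignError(f"cutoffs must be positive and increasing: {self.cutoffs}")
        if self.phase_mode not in ("zero-phase", "single-pass"):
            raise FilterDesignError(f"unknown phase_mode {self.phase_mode!r}")


#: Standard defaults: EDA low-pass 1 Hz, RF low-pass 3 Hz, ECG band-pass 1–30 Hz.
DEFAULT_FILTERS: dict[str, FilterSpec] = {
    "EDA": FilterSpec("EDA", "low-pass", (1.0,)),
    "RF": FilterSpec("RF", "low-pass", (3.0,)),
    "ECG": FilterSpec("ECG", "band-pass", (1.0, 30.0)),
}


def default_filter_spec(modality: str) -> FilterSpec:
    """The standard filter for a modality (EDA 1 Hz LP, RF 3 Hz LP, ECG 1–30 Hz BP)."""
    try:
        return DEFAULT_FILTERS[modality]
    except KeyError:
        raise FilterDesignError(f"no default filter for modality {modality!r}") from None


def _default_numtaps(spec: FilterSpec, fs: float) -> int:
    n = int(round(4.0 * fs / min(spec.cutoffs)))
    n = min(n, MAX_FIR_TAPS)
    if n % 2 == 0:  # Type-I (odd-length) so band-pass gain is unconstrained at Nyquist
        n += 1
    return min(n, MAX_FIR_TAPS if MAX_FIR_TAPS % 2 == 1 else MAX_FIR_TAPS - 1)


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the linear-phase FIR filter for ``spec`` at sampling rate ``fs``.

    Returns the (symmetric) coefficient array. The magnitude response is
    0.5 (−6 dB) at each cutoff, as usual for windowed-sinc designs.
    """
    if fs <= 0:
        raise FilterDesignError(f"fs must be positive, got {fs}")
    if max(spec.cutoffs) >= fs / 2:
        raise FilterDesignError(
            f"cutoff {max(spec.cutoffs)} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    numtaps = spec.order if spec.order is not None else _default_numtaps(spec, fs)
    if numtaps < 3:
        raise FilterDesignError(f"order too small: {numtaps}")
    pass_zero = spec.kind == "low-pass"
    return sps.firwin(numtaps, list(spec.cutoffs), pass_zero=pass_zero, window="hamming", fs=fs)


def filter_signal(record: SignalRecord, spec: FilterSpec | None = None) -> SignalRecord:
    """Apply the modality's FIR filter to a record.

    Zero-phase mode runs the filter forward and backward over a signal
    padded by one filter length of reflected samples at each end, so the
    output has no group delay and no edge transient inside the record.
    """
    if spec is None:
        spec = default_filter_spec(record.modality)
    h = design_fir(spec, record.fs)
    n_taps = h.size
    x = record.samples
    if x.size < 3 * n_taps:
        raise ValueError(
            f"signal ({x.size} samples) shorter than 3 filter lengths "
            f"({3 * n_taps}); use a shorter filter or a longer signal"
        )
    padded = np.pad(x, n_taps, mode="reflect")
    y = sps.oaconvolve(padded, h, mode="same")
    if spec.phase_mode == "zero-phase":
        y = sps.oaconvolve(y[::-1], h, mode="same")[::-1]
    return record.with_samples(y[n_taps:-n_taps])


def normalize_amplitude(record: SignalRecord, mode: str = "unit-energy") -> SignalRecord:
    """Rescale a record's amplitude, then remove its mean.

    ``unit-energy``: x ← x / sqrt(Σ x²) (total energy becomes 1).
    ``literal``:     x ← x / Σ x².
    """
    if mode not in ("unit-energy", "literal"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = record.samples
    energy = float(np.sum(x * x))
    if energy == 0.0:
        raise NormalizationError("cannot normalize a zero-energy signal")
    scaled = x / np.sqrt(energy) if mode == "unit-energy" else x / energy
    return record.with_samples(scaled - scaled.mean())


def decimate_record(record: SignalRecord, target_fs: float) -> SignalRecord:
    """Anti-alias filter and downsample to ``target_fs`` (must divide fs)."""
    factor = record.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"target_fs {target_fs} must integer-divide fs {record.fs}")
    factor = int(round(factor))
    if factor == 1:
        return record
    y = sps.decimate(record.samples, factor, ftype="fir", zero_phase=True)
    out = record.with_samples(y)
    out.fs = target_fs
    return out


def preprocess_record(
    record: SignalRecord,
    spec: FilterSpec | None = None,
    normalization: str = "unit-energy",
) -> SignalRecord:
    """Filter then normalize: the full per-record preprocessing chain."""
    return normalize_amplitude(filter_signal(record, spec), mode=normalization)
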