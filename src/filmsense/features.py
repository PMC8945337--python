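"""Windowed signal-energy features and group energy profiles.

Each preprocessed record is split into contiguous 5-min segments; inside a
segment the power energy EN = Σ |x(n)|² is computed over contiguous
rectangular windows of 5 s (the step equals the width unless overridden).
Window energies are averaged to one value per segment, segment means are
averaged over the subjects of a group, and the two groups' profiles are
finally z-scored *jointly* — pooled mean and pooled population standard
deviation — so the between-group gap survives standardization. A 50-min
recording yields 10 profile points per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SignalRecord

logger = logging.getLogger(__name__)


@dataclass
class EnergySeries:
    """Window energies within one segment of one record."""

    energies: np.ndarray  # one EN value per window, dimensionless after normalization
    segment_index: int
    window_s: float
    subject_id: str = ""
    modality: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)


@dataclass
class GroupProfile:
    """Per-segment group-mean energies for one group and modality."""

    points: np.ndarray  # length = number of segments (10 for a 50-min session)
    group: str
    modality: str = ""
    zscored: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)


def segment_signal(record: SignalRecord, segment_min: float = 5.0) -> list[np.ndarray]:
    """Split a record into contiguous, non-overlapping ``segment_min`` blocks.

    The trailing remainder shorter than one segment is dropped (and logged).
    """
    seg_len = int(round(segment_min * 60.0 * record.fs))
    if seg_len < 1:
        raise ValueError(f"segment length {segment_min} min is below one sample")
    n = record.n_samples
    n_segments = n // seg_len
    if n_segments == 0:
        raise ValueError(
            f"record of {record.duration_s / 60.0:.2f} min is shorter than one "
            f"{segment_min}-min segment; at least {segment_min} min required"
        )
    remainder = n - n_segments * seg_len
    if remainder:
        logger.debug(
            "dropping %.2f min remainder after %d segments of %s min",
            remainder / record.fs / 60.0, n_segments, segment_min,
        )
    return [record.samples[i * seg_len : (i + 1) * seg_len] for i in range(n_segments)]


def window_energy(
    segment: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    step_s: float | None = None,
    segment_index: int = 0,
    **labels: str,
) -> EnergySeries:
    """Power energy EN = Σ |x(n)|² over rectangular windows of ``window_s``.

    Windows advance by ``step_s`` (default: the window width, i.e.
    contiguous and non-overlapping). Samples beyond the last whole window
    are dropped.
    """
    segment = np.asarray(segment, dtype=np.float64)
    w = int(round(window_s * fs))
    step = w if step_s is None else int(round(step_s * fs))
    if w < 1 or step < 1:
        raise ValueError("window and step must be at least one sample")
    if w > segment.size:
        raise ValueError(f"window ({w} samples) longer than segment ({segment.size})")
    sq = segment * segment
    if step == w:  # contiguous windows: direct block sums (no cumsum cancellation)
        k = segment.size // w
        energies = sq[: k * w].reshape(k, w).sum(axis=1)
    else:
        starts = np.arange(0, segment.size - w + 1, step)
        csum = np.concatenate(([0.0], np.cumsum(sq)))
        energies = csum[starts + w] - csum[starts]
    return EnergySeries(
        energies=energies, segment_index=segment_index, window_s=window_s, **labels
    )


def segment_mean_energy(series: EnergySeries) -> float:
    """Arithmetic mean of a segment's window energies."""
    if series.energies.size == 0:
        raise ValueError("cannot average an empty energy series")
    return float(series.energies.mean())


def subject_segment_means(
    record: SignalRecord, segment_min: float = 5.0, window_s: float = 5.0,
    step_s: float | None = None,
) -> np.ndarray:
    """One mean energy per segment for a single (preprocessed) record."""
    segments = segment_signal(record, segment_min)
    return np.array(
        [
            segment_mean_energy(
                window_energy(seg, record.fs, window_s, step_s, segment_index=i)
            )
            for i, seg in enumerate(segments)
        ]
    )


def group_mean_profile(per_subject_segment_means: np.ndarray, group: str,
                       modality: str = "") -> GroupProfile:
    """Average a (subject × segment) matrix of mean energies over subjects."""
    m = np.asarray(per_subject_segment_means, dtype=np.float64)
    if m.size == 0:
        raise ValueError("empty segment-mean matrix")
    if m.ndim == 1:
        m = m[np.newaxis, :]
    if m.ndim != 2:
        raise ValueError(f"expected a subject × segment matrix, got shape {m.shape}")
    return GroupProfile(points=m.mean(axis=0), group=group, modality=modality)


def stack_common_segments(rows: list[np.ndarray]) -> np.ndarray:
    """Stack per-subject segment means, truncating to the common minimum count."""
    if not rows:
        raise ValueError("no subjects")
    n_min = min(r.size for r in rows)
    if n_min == 0:
        raise ValueError("a subject contributed zero segments")
    if any(r.size != n_min for r in rows):
        logger.info("truncating subjects to the common minimum of %d segments", n_min)
    return np.vstack([r[:n_min] for r in rows])


def zscore_joint(
    profile_a: GroupProfile, profile_b: GroupProfile
) -> tuple[GroupProfile, GroupProfile]:
    """Standardize two group profiles by their pooled mean and population sd.

    After the transform the pooled 2n points have mean 0 and sd 1, and every
    between-group ordering of point values is preserved (the map is affine
    and increasing).
    """
    a, b = profile_a.points, profile_b.points
    if a.size != b.size:
        raise ValueError(f"profiles have different lengths: {a.size} vs {b.size}")
    pooled = np.concatenate([a, b])
    mu = pooled.mean()
    sd = pooled.std()  # population (divide-by-n) convention
    if sd == 0.0:
        raise ValueError("pooled standard deviation is zero; cannot z-score")
    za = GroupProfile((a - mu) / sd, profile_a.group, profile_a.modality, zscored=True)
    zb = GroupProfile((b - mu) / sd, profile_b.group, profile_b.modality, zscored=True)
    return za, zb


def profiles_to_frame(raw: dict[str, GroupProfile], z: dict[str, GroupProfile]) -> pd.DataFrame:
    """Tidy feature table: segment_index, group, modality, mean_energy, zscored_energy."""
    rows = []
    for key, prof in raw.items():
        zprof = z[key]
        for j, (e, ze) in enumerate(zip(prof.points, zprof.points)):
            rows.append(
                {
                    "segment_index": j,
                    "group": prof.group,
                    "modality": prof.modality,
                    "mean_energy": e,
                    "zscored_energy": ze,
                }
            )
    return pd.DataFrame(rows)
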