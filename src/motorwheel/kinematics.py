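"""Forelimb kinematics: paw centering, stride detection, coordination.

Paw positions come from markerless pose tracking as pixel coordinates per
video frame (~71.5 Hz).  Each coordinate series is centered on its median and
converted to millimetres, ``d_new = alpha * (d_median - d_raw)``, so that
forward positions are positive.  A stride is the rising phase of a spike in
the horizontal (x) trace that co-occurs with a complete spike in the vertical
(y) trace; stride length is the x excursion from the preceding trough to the
peak.  Interlimb coordination is scored as the negative Pearson correlation
of the two forepaws' centered horizontal traces within a speed block, so +1
means perfect alternation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .profile import SpeedProfile

__all__ = [
    "PawTrajectory",
    "CenteredTrace",
    "StrideSet",
    "center_paw",
    "smooth_trace",
    "detect_strides",
    "block_stride_stats",
    "percent_change",
    "coordination_index",
]


@dataclass
class PawTrajectory:
    """Raw pixel coordinates of one forepaw per video frame."""

    frame_rate: float
    x_raw: np.ndarray
    y_raw: np.ndarray
    paw_label: str = "left"

    def __post_init__(self) -> None:
        self.x_raw = np.asarray(self.x_raw, dtype=float)
        self.y_raw = np.asarray(self.y_raw, dtype=float)
        if self.x_raw.shape != self.y_raw.shape or self.x_raw.ndim != 1:
            raise ValueError("x_raw and y_raw must be 1-D series of equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.x_raw)


@dataclass
class CenteredTrace:
    """Median-centered paw location in millimetres, forward positive."""

    values_mm: np.ndarray
    alpha: float
    d_median: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.values_mm = np.asarray(self.values_mm, dtype=float)

    def __len__(self) -> int:
        return len(self.values_mm)


@dataclass
class StrideSet:
    """Detected strides: one row per stride (start/end frame, length in mm)."""

    strides: pd.DataFrame  # columns: start_frame, peak_frame, end_frame, length_mm
    frame_rate: float

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    @property
    def lengths_mm(self) -> np.ndarray:
        return self.strides["length_mm"].to_numpy()


def center_paw(series: np.ndarray, alpha: float, frame_rate: float = 71.5) -> CenteredTrace:
    """Center a raw coordinate series on its median and convert to mm.

    Applies ``d_new[t] = alpha * (median(d_raw) - d_raw[t])`` where ``d_raw``
    is the pixel distance of the paw from the image corner and ``alpha`` is
    the mm-per-pixel calibration; the median paw position maps to zero and
    forward positions are positive.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (mm per pixel)")
    d_raw = np.asarray(series, dtype=float)
    if d_raw.size == 0:
        raise ValueError("empty coordinate series")
    d_median = float(np.median(d_raw))
    return CenteredTrace(alpha * (d_median - d_raw), alpha, d_median, frame_rate)


def smooth_trace(series: np.ndarray, order: int = 2, cutoff: float = 0.1) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of a coordinate series.

    ``cutoff`` is a fraction of the Nyquist frequency.  The filter is applied
    forward and backward (filtfilt), so it introduces no lag between the two
    paws' traces.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie strictly between 0 and 1 (fraction of Nyquist)")
    x = np.asarray(series, dtype=float)
    b, a = signal.butter(order, cutoff)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"series of length {len(x)} too short for order-{order} filtering")
    return signal.filtfilt(b, a, x)


def detect_strides(
    x: CenteredTrace,
    y: CenteredTrace,
    min_prominence: float | None = None,
    min_separation: int | None = None,
) -> StrideSet:
    """Detect strides from centered horizontal (x) and vertical (y) traces.

    A stride is emitted where a prominent local maximum of y (a complete
    vertical spike of the swing phase) falls inside the rising phase of an
    x spike, i.e. between an x trough and the following x peak.  The stride
    spans trough to peak and its length is ``x[peak] - x[trough]`` in mm.

    Defaults, chosen to be scale-free: ``min_prominence`` is half the
    interquartile range of the y trace, ``min_separation`` is 0.1 s of frames.
    """
    xv = x.values_mm
    yv = y.values_mm
    if len(xv) != len(yv):
        raise ValueError("x and y traces must have equal length")
    if x.frame_rate != y.frame_rate:
        raise ValueError("x and y traces must share a frame rate")
    if min_separation is None:
        min_separation = max(1, int(round(0.1 * x.frame_rate)))
    def _scale(v: np.ndarray) -> float:
        # robust spike scale; falls back to half the range for sparse spikes
        iqr = stats.iqr(v)
        return 0.5 * iqr if iqr > 0 else 0.5 * float(np.ptp(v))

    if min_prominence is None:
        min_prominence = _scale(yv)

    empty = pd.DataFrame(columns=["start_frame", "peak_frame", "end_frame", "length_mm"])
    if min_prominence <= 0:
        return StrideSet(empty, x.frame_rate)

    y_peaks, _ = signal.find_peaks(yv, prominence=min_prominence, distance=min_separation)
    x_prom = _scale(xv)
    if x_prom <= 0:
        return StrideSet(empty, x.frame_rate)
    x_peaks, _ = signal.find_peaks(xv, prominence=x_prom, distance=min_separation)
    if len(y_peaks) == 0 or len(x_peaks) == 0:
        return StrideSet(empty, x.frame_rate)

    rows = []
    used_x_peaks: set[int] = set()
    for yp in y_peaks:
        # first x peak at or after the y spike: end of the rising phase
        k = np.searchsorted(x_peaks, yp)
        if k == len(x_peaks):
            continue
        xp = int(x_peaks[k])
        if xp in used_x_peaks:
            continue
        lo = int(x_peaks[k - 1]) + 1 if k > 0 else 0
        trough = lo + int(np.argmin(xv[lo : xp + 1]))
        if not (trough <= yp <= xp):
            continue
        length = float(xv[xp] - xv[trough])
        if length <= 0:
            continue
        used_x_peaks.add(xp)
        rows.append((trough, xp, xp, length))

    rows.sort()
    df = pd.DataFrame(rows, columns=["start_frame", "peak_frame", "end_frame", "length_mm"])
    return StrideSet(df, x.frame_rate)


def block_stride_stats(strides: StrideSet, profile: SpeedProfile) -> pd.DataFrame:
    """Per-block stride counts and mean lengths.

    Strides are assigned to speed blocks by the frame of their x peak.  A
    block with no strides reports a missing (NaN) mean length.
    """
    slices = profile.block_slices(strides.frame_rate)
    n_frames = profile.n_frames(strides.frame_rate)
    if strides.n_strides and strides.strides["peak_frame"].max() >= n_frames:
        raise ValueError("stride frames extend past the end of the speed profile")
    records = []
    peaks = strides.strides["peak_frame"].to_numpy() if strides.n_strides else np.array([], int)
    lengths = strides.lengths_mm
    for i, sl in enumerate(slices):
        mask = (peaks >= sl.start) & (peaks < sl.stop)
        count = int(mask.sum())
        mean_len = float(np.mean(lengths[mask])) if count else np.nan
        records.append(
            {
                "block": i,
                "speed_mm_s": profile.speeds[i],
                "stride_count": count,
                "mean_length_mm": mean_len,
            }
        )
    return pd.DataFrame(records)


def percent_change(earlier: float, later: float) -> float:
    """(later - earlier) / earlier * 100."""
    if earlier == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return (later - earlier) / earlier * 100.0


def coordination_index(
    left: CenteredTrace,
    right: CenteredTrace,
    block: slice | None = None,
) -> float:
    """Negative Pearson correlation of the two forepaw traces within a block.

    +1 means perfect alternation (anti-phase), -1 perfect in-phase movement.
    Raises if either trace has zero variance in the block.
    """
    l = left.values_mm if block is None else left.values_mm[block]
    r = right.values_mm if block is None else right.values_mm[block]
    if len(l) != len(r):
        raise ValueError("traces must cover the same block")
    if np.std(l) == 0 or np.std(r) == 0:
        raise ValueError("coordination index undefined for a zero-variance trace")
    return float(-np.corrcoef(l, r)[0, 1])
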