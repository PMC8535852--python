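"""Calcium event detection and rate analyses.

ΔF/F traces (neurons x frames, ~6-7 frames/s) are binarized into event
rasters with a transparent threshold rule: an event onset is an upward
crossing of baseline + k * MAD that stays above threshold for a minimum
number of frames, with the baseline a per-neuron running median.  Downstream
analyses (block-wise rates, the full-width-at-half-maximum of the rate
distribution, and peri-transition rate changes) consume rasters and are
agnostic to how the raster was produced, so externally deconvolved rasters
can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .profile import SpeedProfile

__all__ = [
    "TraceMatrix",
    "EventRaster",
    "detect_events",
    "block_event_rate",
    "state_rates",
    "rate_distribution_width",
    "FWHMResult",
    "transition_rate_change",
]

# MAD -> standard-deviation scale for a Gaussian
_MAD_SCALE = 1.4826


@dataclass
class TraceMatrix:
    """ΔF/F traces with per-neuron layer and centroid metadata.

    ``dff`` is neurons x frames.  ``layer`` labels each neuron (e.g. "L2/3"
    or "L5a"); ``centroids`` are (x, y) pixel positions in the imaging field
    and ``pixel_size_um`` converts pixel distances to micrometres.
    """

    dff: np.ndarray
    frame_rate: float
    layer: np.ndarray | None = None
    centroids: np.ndarray | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("ΔF/F traces contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 5.0 <= self.frame_rate <= 10.0:
            warnings.warn(
                f"frame rate {self.frame_rate:.2f} Hz outside the usual 5-10 Hz"
                " per-layer acquisition range",
                stacklevel=2,
            )
        if self.layer is not None:
            self.layer = np.asarray(self.layer)
            if len(self.layer) != self.n_neurons:
                raise ValueError("one layer label per neuron required")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (self.n_neurons, 2):
                raise ValueError("centroids must be (n_neurons, 2)")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class EventRaster:
    """Binary event-onset raster, same shape as its source traces."""

    events: np.ndarray
    frame_rate: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.atleast_2d(np.asarray(self.events, dtype=bool))

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]

    @property
    def n_frames(self) -> int:
        return self.events.shape[1]


def detect_events(
    traces: TraceMatrix,
    k_mad: float = 2.5,
    min_duration_frames: int = 2,
    baseline_window_s: float = 30.0,
) -> EventRaster:
    """Mark event onsets where ΔF/F crosses a robust per-neuron threshold.

    Threshold = running-median baseline + ``k_mad`` x MAD (MAD scaled to the
    Gaussian sigma).  An onset is the first frame of an excursion that stays
    above threshold for at least ``min_duration_frames``.  Because the slow
    decay of the indicator can merge closely spaced transients into a single
    supra-threshold excursion, an additional onset is marked wherever the
    trace jumps upward by more than ``k_mad x MAD x sqrt(2)`` (the threshold
    on a one-frame difference) while already above threshold.  Adding a
    constant to a trace leaves the raster unchanged.
    """
    dff = traces.dff
    n, t = dff.shape
    win = max(3, int(round(baseline_window_s * traces.frame_rate)) | 1)  # odd
    win = min(win, t if t % 2 else t - 1) if t > 1 else 1
    baseline = ndimage.median_filter(dff, size=(1, win), mode="nearest")
    resid = dff - baseline
    mad = np.median(np.abs(resid), axis=1, keepdims=True) * _MAD_SCALE
    above = resid > k_mad * mad

    events = np.zeros_like(above)
    for i in range(n):
        a = above[i]
        if not a.any():
            continue
        edges = np.diff(a.astype(np.int8))
        starts = np.nonzero(edges == 1)[0] + 1
        ends = np.nonzero(edges == -1)[0] + 1
        if a[0]:
            starts = np.r_[0, starts]
        if a[-1]:
            ends = np.r_[ends, t]
        keep = (ends - starts) >= min_duration_frames
        events[i, starts[keep]] = True
        # split merged transients: re-excitation jumps inside a kept run
        if mad[i, 0] > 0:
            jump = np.diff(dff[i]) > np.sqrt(2.0) * k_mad * mad[i, 0]
            for s0, e0 in zip(starts[keep], ends[keep]):
                inside = np.nonzero(jump[s0 : e0 - 1])[0]
                events[i, s0 + 1 + inside] = True

    params = {
        "k_mad": k_mad,
        "min_duration_frames": min_duration_frames,
        "baseline_window_s": baseline_window_s,
        "rate_counts": "onsets",
    }
    return EventRaster(events, traces.frame_rate, params)


def block_event_rate(raster: EventRaster, profile: SpeedProfile) -> pd.DataFrame:
    """Per-neuron event rate (events/s) in each speed block.

    Returns a long-format frame with columns neuron, block, speed_mm_s and
    rate_hz.  Block rates are onset counts divided by block duration.
    """
    if raster.n_frames < profile.n_frames(raster.frame_rate):
        raise ValueError("raster shorter than the speed profile")
    slices = profile.block_slices(raster.frame_rate)
    rows = []
    for b, sl in enumerate(slices):
        dur = (sl.stop - sl.start) / raster.frame_rate
        if dur <= 0:
            raise ValueError(f"block {b} has zero duration at this frame rate")
        counts = raster.events[:, sl].sum(axis=1)
        for neuron, c in enumerate(counts):
            rows.append((neuron, b, profile.speeds[b], c / dur))
    return pd.DataFrame(rows, columns=["neuron", "block", "speed_mm_s", "rate_hz"])


def state_rates(raster: EventRaster, profile: SpeedProfile) -> pd.DataFrame:
    """Per-neuron rest vs running rates: rest pools the speed-0 blocks,
    running pools all nonzero-speed blocks (events / pooled duration)."""
    slices = profile.block_slices(raster.frame_rate)
    out = {}
    for state, pick in (("rest", lambda s: s == 0), ("running", lambda s: s > 0)):
        blocks = [sl for sl, sp in zip(slices, profile.speeds) if pick(sp)]
        frames = sum(sl.stop - sl.start for sl in blocks)
        counts = sum(
            (raster.events[:, sl].sum(axis=1) for sl in blocks),
            start=np.zeros(raster.n_neurons),
        )
        out[state] = counts / (frames / raster.frame_rate) if frames else np.full(
            raster.n_neurons, np.nan
        )
    return pd.DataFrame({"neuron": np.arange(raster.n_neurons), **out})


@dataclass
class FWHMResult:
    """Full width at half maximum of a rate histogram."""

    width: float
    bin_width: float
    multimodal: bool

    def __float__(self) -> float:
        return self.width


def rate_distribution_width(
    rates: np.ndarray,
    bin_width: float | None = None,
    smooth_sigma_bins: float = 1.0,
) -> FWHMResult:
    """Width of the event-rate distribution as FWHM of its histogram.

    The histogram (Freedman-Diaconis bins by default) is lightly smoothed and
    the width of its highest peak at half height is measured with
    ``scipy.signal.peak_widths``.  A multimodal histogram is flagged and the
    width of the highest peak reported.  Degenerate all-equal rates yield one
    bin width.
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 10:
        raise ValueError("need at least 10 rate values for a histogram width")
    if bin_width is None:
        iqr = stats.iqr(r)
        bin_width = 2 * iqr / len(r) ** (1 / 3) if iqr > 0 else 0.0
    if bin_width <= 0:
        # all values (essentially) identical: the width is one nominal bin
        bw = max(abs(r.mean()) * 1e-3, 1e-9)
        return FWHMResult(bw, bw, multimodal=False)
    lo, hi = r.min() - bin_width, r.max() + bin_width
    nbins = max(3, int(np.ceil((hi - lo) / bin_width)))
    counts, _ = np.histogram(r, bins=nbins, range=(lo, hi))
    smoothed = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma_bins)
    # pad so a boundary mode is still a proper peak for peak_widths
    padded = np.r_[0.0, smoothed, 0.0]
    peaks, props = signal.find_peaks(padded, height=0)
    if len(peaks) == 0:
        return FWHMResult(bin_width, bin_width, multimodal=False)
    heights = props["peak_heights"]
    top = peaks[int(np.argmax(heights))]
    widths = signal.peak_widths(padded, [top], rel_height=0.5)[0]
    multimodal = int((heights > 0.5 * heights.max()).sum()) > 1
    return FWHMResult(float(widths[0]) * bin_width, bin_width, multimodal)


def transition_rate_change(
    raster: EventRaster,
    profile: SpeedProfile,
    post_s: float = 10.0,
    pre_s: float = 5.0,
) -> pd.DataFrame:
    """Event rates just before and after each speed transition.

    For each transition at time t the pre window is [t - pre_s, t) and the
    post window [t, t + post_s).  A neuron is transition-associated at t if
    its post rate strictly exceeds its pre rate (ties are not associated).
    Transitions whose windows fall off the recording are skipped with a
    warning.
    """
    fr = raster.frame_rate
    rows = []
    for k, t in enumerate(profile.transition_times_s):
        f = int(round(t * fr))
        pre_lo = f - int(round(pre_s * fr))
        post_hi = f + int(round(post_s * fr))
        if pre_lo < 0 or post_hi > raster.n_frames:
            warnings.warn(f"transition {k} at {t:.0f}s too close to the recording edge; skipped")
            continue
        pre = raster.events[:, pre_lo:f].sum(axis=1) / ((f - pre_lo) / fr)
        post = raster.events[:, f:post_hi].sum(axis=1) / ((post_hi - f) / fr)
        for neuron in range(raster.n_neurons):
            rows.append(
                (
                    neuron,
                    k,
                    t,
                    pre[neuron],
                    post[neuron],
                    bool(post[neuron] > pre[neuron]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["neuron", "transition", "time_s", "pre_rate_hz", "post_rate_hz", "associated"],
    )
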