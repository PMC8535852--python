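"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its seed and emulates one of the three
experimental input kinds:

* paw trajectories — stride trains (a linear rise in x co-occurring with a
  half-sine spike in y per stride) at the frame rate of the behaviour camera,
  with a controllable interlimb coordination and planted stride times;
* ΔF/F trace matrices — either a stationary Gaussian latent process whose
  conditional-independence structure encodes a planted direct-coupling graph
  (for connectivity inference), or Bernoulli event trains with planted
  transition responders, both convolved with a single-exponential calcium
  kernel;
* per-day ROI tables — day-1 centroids plus planted integer field-of-view
  shifts, per-neuron jitter and dropout, with the identity map recorded.

Planted quantities are exactly recoverable at zero noise by the
corresponding analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .events import EventRaster, TraceMatrix
from .kinematics import PawTrajectory
from .profile import SpeedProfile
from .registration import ROITable

__all__ = [
    "GroundTruth",
    "gen_paw_trajectories",
    "gen_network_traces",
    "gen_transition_responders",
    "gen_roi_sessions",
    "chain_coupling",
    "random_coupling",
    "distance_decay_coupling",
    "coupling_covariance",
    "default_strides_per_block",
]

# camera rate of the behaviour videos (Hz)
PAW_FRAME_RATE = 71.5
# two-photon per-layer rate chosen so a 12-min session has 4630 frames
CALCIUM_FRAME_RATE = 4630 / 720.0
DEFAULT_ALPHA_MM_PER_PX = 0.1
DEFAULT_KERNEL_TAU_S = 0.6  # GCaMP6m-like single-exponential decay


@dataclass
class GroundTruth:
    """Planted quantities recorded by the generators."""

    stride_times: list | None = None  # (paw, start_frame, peak_frame, length_mm)
    coupling: np.ndarray | None = None
    responder_labels: np.ndarray | None = None
    event_raster: EventRaster | None = None
    day_shifts: list | None = None  # per-day integer (dx, dy)
    identity_map: dict | None = None  # day -> {stable id: per-day ROI id}

    def __post_init__(self) -> None:
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=float)
            if not np.allclose(c, c.T) or np.any(np.diag(c) != 0):
                raise ValueError("coupling graph must be symmetric with zero diagonal")
            self.coupling = c


# ---------------------------------------------------------------------------
# paw trajectories


def default_strides_per_block(profile: SpeedProfile) -> list[int]:
    """Stride counts per block matching wild-type group means.

    Reported means are ~271.8 strides per 2-min block at 15 mm/s and ~475.7
    at 60 mm/s; counts at other speeds are linearly interpolated
    (count ~ 203.8 + 4.53 * speed) and scaled to the block duration.
    """
    scale = profile.block_duration_s / 120.0
    return [
        0 if s == 0 else int(round((203.8 + 4.531 * s) * scale)) for s in profile.speeds
    ]


def _stride_train(
    profile: SpeedProfile,
    strides_per_block: list[int],
    stride_length_mm: float,
    spike_height_mm: float,
    frame_rate: float,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Noise-free x/y stride waveforms plus (start, peak, length) triples.

    Each stride is a linear rise of x from 0 to stride_length_mm over D
    frames with a half-sine y spike on the rise, followed by a linear fall
    back to baseline; strides are evenly spaced within their block, offset
    by ``phase`` (fraction of the stride spacing).
    """
    n = profile.n_frames(frame_rate)
    x = np.zeros(n)
    y = np.zeros(n)
    strides: list = []
    for sl, count in zip(profile.block_slices(frame_rate), strides_per_block):
        if count <= 0:
            continue
        span = sl.stop - sl.start
        spacing = span / count
        d = max(2, int(spacing * 0.4))  # rise (and fall) duration in frames
        for k in range(count):
            start = sl.start + int(round((k + 0.1 + phase % 1.0) * spacing))
            peak = start + d
            end = peak + d
            if end >= sl.stop:
                break
            ramp = np.linspace(0.0, stride_length_mm, d + 1)
            x[start : peak + 1] = ramp
            x[peak : end + 1] = ramp[::-1]
            y[start : peak + 1] = spike_height_mm * np.sin(
                np.linspace(0.0, np.pi, d + 1)
            )
            strides.append((start, peak, stride_length_mm))
    return x, y, strides


def _to_raw_px(
    centered_mm: np.ndarray, alpha: float, median_px: float
) -> np.ndarray:
    # invert d_new = alpha * (median - raw); the realized median may differ
    # slightly from median_px, which is irrelevant after re-centering
    return median_px - centered_mm / alpha


def gen_paw_trajectories(
    profile: SpeedProfile,
    strides_per_block: list[int] | int | None = None,
    stride_length_mm: float = 4.5,
    spike_height_mm: float = 3.0,
    coordination: float = 0.0,
    noise_sd_mm: float = 0.0,
    seed: int | None = None,
    frame_rate: float = PAW_FRAME_RATE,
    alpha: float = DEFAULT_ALPHA_MM_PER_PX,
) -> tuple[PawTrajectory, PawTrajectory, GroundTruth]:
    """Two forepaw trajectories with planted strides and coordination.

    The left paw carries the planted stride train.  The right paw's x trace
    is a mixture ``c * (-left) + sqrt(1 - c^2) * g`` of the mirrored left
    trace and an independent, phase-shifted stride train g (standardized to
    the left trace's variance), so the expected coordination index equals
    ``coordination``; its y trace is g's spike train.  Ground truth records
    left-paw stride times always, and right-paw times only when the right
    trace is a pure train (coordination 0 or ±1).
    """
    if not -1.0 <= coordination <= 1.0:
        raise ValueError("coordination must lie in [-1, 1]")
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be nonnegative")
    if strides_per_block is None:
        strides_per_block = default_strides_per_block(profile)
    elif np.isscalar(strides_per_block):
        strides_per_block = [
            int(strides_per_block) if s > 0 else 0 for s in profile.speeds
        ]
    if any(c < 0 for c in strides_per_block):
        raise ValueError("stride counts must be nonnegative")
    if len(strides_per_block) != profile.n_blocks:
        raise ValueError("one stride count per block required")

    rng = np.random.default_rng(seed)
    lx, ly, left_strides = _stride_train(
        profile, strides_per_block, stride_length_mm, spike_height_mm, frame_rate
    )
    # independent right-paw train: a seed-drawn phase and slightly different
    # stride cadence decorrelate it from the left train
    cadence = float(rng.uniform(0.8, 1.25))
    g_counts = [int(round(c * cadence)) if c > 0 else 0 for c in strides_per_block]
    gx, gy, g_strides = _stride_train(
        profile,
        strides_per_block=g_counts,
        stride_length_mm=stride_length_mm,
        spike_height_mm=spike_height_mm,
        frame_rate=frame_rate,
        phase=float(rng.uniform(0.0, 0.8)),
    )

    c = coordination
    if np.std(gx) > 0 and np.std(lx) > 0:
        gx_std = (gx - gx.mean()) / np.std(gx) * np.std(lx)
    else:
        gx_std = gx
    rx = c * (-(lx - lx.mean())) + np.sqrt(1 - c**2) * gx_std
    ry = gy

    stride_times: list = [("left", s, p, l) for s, p, l in left_strides]
    if c == 0.0:
        stride_times += [("right", s, p, l) for s, p, l in g_strides]

    def _traj(xc: np.ndarray, yc: np.ndarray, label: str) -> PawTrajectory:
        xn = xc + rng.normal(0, noise_sd_mm, len(xc)) if noise_sd_mm else xc
        yn = yc + rng.normal(0, noise_sd_mm, len(yc)) if noise_sd_mm else yc
        return PawTrajectory(
            frame_rate,
            _to_raw_px(xn, alpha, 300.0),
            _to_raw_px(yn, alpha, 200.0),
            label,
        )

    truth = GroundTruth(stride_times=stride_times)
    return _traj(lx, ly, "left"), _traj(rx, ry, "right"), truth


# ---------------------------------------------------------------------------
# coupled network traces


def chain_coupling(n: int, rho: float) -> np.ndarray:
    """Chain graph 0-1-...-(n-1) with coupling ``rho`` on each edge."""
    c = np.zeros((n, n))
    for i in range(n - 1):
        c[i, i + 1] = c[i + 1, i] = rho
    return c


def random_coupling(
    n: int,
    density: float = 0.1,
    strength: float = 0.3,
    seed: int | None = None,
    random_signs: bool = False,
) -> np.ndarray:
    """Erdos-Renyi coupling graph with fixed-magnitude edge weights."""
    rng = np.random.default_rng(seed)
    c = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    edges = rng.random(len(iu[0])) < density
    w = np.full(edges.sum(), strength)
    if random_signs:
        w *= rng.choice([-1.0, 1.0], size=len(w))
    c[iu[0][edges], iu[1][edges]] = w
    return c + c.T


def distance_decay_coupling(
    centroids_px: np.ndarray,
    pixel_size_um: float,
    strength: float = 0.3,
    length_um: float = 80.0,
    base_prob: float = 0.6,
    seed: int | None = None,
) -> np.ndarray:
    """Coupling graph whose edge probability decays with somatic distance."""
    rng = np.random.default_rng(seed)
    xy = np.asarray(centroids_px, dtype=float) * pixel_size_um
    n = len(xy)
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    c = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    p = base_prob * np.exp(-d[iu] / length_um)
    edges = rng.random(len(p)) < p
    c[iu[0][edges], iu[1][edges]] = strength
    return c + c.T


def coupling_covariance(
    coupling: np.ndarray,
    mode: str = "precision",
    condition: bool = False,
    min_eig: float = 0.05,
) -> np.ndarray:
    """Correlation matrix of the Gaussian latent process for a coupling graph.

    ``mode="markov"`` (forest graphs only): the coupling is the marginal
    correlation of each edge and the correlation of any pair is the product
    of couplings along their path (zero across components) — the Gaussian
    Markov construction, whose precision is supported exactly on the graph.

    ``mode="precision"``: the coupling is the requested partial correlation;
    the precision matrix is I - C, which requires the spectral radius of C
    to be below 1.  With ``condition=True`` an insufficiently positive
    definite precision is inflated along the diagonal and re-standardized,
    preserving the zero pattern and the ranking of edge strengths (the
    realized partial correlations shrink accordingly).
    """
    c = np.asarray(coupling, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n) or not np.allclose(c, c.T):
        raise ValueError("coupling matrix must be square and symmetric")
    if np.any(np.diag(c) != 0):
        raise ValueError("coupling matrix must have a zero diagonal")

    if mode == "markov":
        g = nx.from_numpy_array(np.abs(c) > 0)
        if not nx.is_forest(g):
            raise ValueError('mode="markov" requires an acyclic (forest) coupling graph')
        sigma = np.eye(n)
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            for i in nodes:
                lengths = nx.single_source_shortest_path(g, i)
                for j, path in lengths.items():
                    if j <= i:
                        continue
                    prod = 1.0
                    for a, b in zip(path[:-1], path[1:]):
                        prod *= c[a, b]
                    sigma[i, j] = sigma[j, i] = prod
        return sigma

    if mode != "precision":
        raise ValueError(f"unknown coupling mode {mode!r}")
    p = np.eye(n) - c
    lam = np.linalg.eigvalsh(p)[0]
    if lam <= 1e-9:
        if not condition:
            raise ValueError(
                "unstable coupling matrix: spectral radius >= 1 (precision not"
                " positive definite); reduce couplings or pass condition=True"
            )
        p = p + (min_eig - lam) * np.eye(n)
        d = np.sqrt(np.diag(p))
        p = p / np.outer(d, d)
    sigma = np.linalg.inv(p)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _exp_kernel_filter(x: np.ndarray, tau_s: float, frame_rate: float) -> np.ndarray:
    """Convolve each row with a causal exponential kernel exp(-t / tau).

    Implemented as the IIR recursion y[t] = x[t] + a y[t-1] with
    a = exp(-1 / (tau * frame_rate)).  Applying the same linear filter to
    every neuron preserves zero-lag correlations of white-in-time input.
    """
    a = np.exp(-1.0 / (tau_s * frame_rate))
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -a], x, axis=-1)


def gen_network_traces(
    n_neurons: int,
    coupling: np.ndarray,
    frames: int = 4630,
    frame_rate: float = CALCIUM_FRAME_RATE,
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S,
    noise_sd: float = 0.0,
    seed: int | None = None,
    mode: str = "precision",
    condition: bool = False,
    layer: np.ndarray | None = None,
    centroids: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> tuple[TraceMatrix, GroundTruth]:
    """Trace matrix from a stationary Gaussian latent network process.

    Per-frame latent activity is multivariate normal with the correlation
    structure implied by the coupling graph (see
    :func:`coupling_covariance`); traces are the latent series convolved
    with a single-exponential calcium kernel plus white observation noise.
    """
    import warnings

    c = np.asarray(coupling, dtype=float)
    if c.shape != (n_neurons, n_neurons):
        raise ValueError("coupling matrix must be n_neurons x n_neurons")
    if frames < n_neurons:
        warnings.warn(
            f"{frames} frames for {n_neurons} neurons: downstream covariance"
            " estimates will be ill-conditioned"
        )
    sigma = coupling_covariance(c, mode=mode, condition=condition)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(n_neurons))
    latent = chol @ rng.standard_normal((n_neurons, frames))
    dff = _exp_kernel_filter(latent, kernel_tau_s, frame_rate)
    if noise_sd > 0:
        dff = dff + rng.normal(0, noise_sd, dff.shape)
    traces = TraceMatrix(dff, frame_rate, layer, centroids, pixel_size_um)
    return traces, GroundTruth(coupling=c)


# ---------------------------------------------------------------------------
# transition responders


def gen_transition_responders(
    profile: SpeedProfile,
    n_neurons: int,
    responder_fraction: float = 0.2,
    effect_rate_gain: float = 4.0,
    baseline_rate_hz: float = 0.1,
    window_s: float = 15.0,
    frame_rate: float = CALCIUM_FRAME_RATE,
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[TraceMatrix, GroundTruth]:
    """Event-train traces with a planted fraction of transition responders.

    Non-responders fire as homogeneous Bernoulli trains at
    ``baseline_rate_hz``; responders fire at ``baseline x gain`` inside the
    ``window_s`` windows after each speed transition and at baseline
    elsewhere.  Traces are the event trains convolved with the calcium
    kernel; the planted labels and the event raster are recorded.
    """
    if not 0 <= responder_fraction <= 1:
        raise ValueError("responder_fraction must lie in [0, 1]")
    if effect_rate_gain < 1:
        raise ValueError("effect_rate_gain must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames = profile.n_frames(frame_rate)
    n_resp = int(round(responder_fraction * n_neurons))
    labels = np.zeros(n_neurons, dtype=bool)
    labels[rng.choice(n_neurons, n_resp, replace=False)] = True

    in_window = np.zeros(n_frames, dtype=bool)
    w = int(round(window_s * frame_rate))
    for f in profile.transition_frames(frame_rate):
        in_window[f : min(n_frames, f + w)] = True

    p_base = baseline_rate_hz / frame_rate
    p = np.full((n_neurons, n_frames), p_base)
    p[np.ix_(labels, in_window)] = min(1.0, p_base * effect_rate_gain)
    events = rng.random((n_neurons, n_frames)) < p

    dff = _exp_kernel_filter(events.astype(float) * amplitude, kernel_tau_s, frame_rate)
    if noise_sd > 0:
        dff = dff + rng.normal(0, noise_sd, dff.shape)
    traces = TraceMatrix(dff, frame_rate)
    raster = EventRaster(events, frame_rate, {"planted": True})
    return traces, GroundTruth(responder_labels=labels, event_raster=raster)


# ---------------------------------------------------------------------------
# ROI sessions


def gen_roi_sessions(
    n_neurons: int,
    n_days: int,
    field_px: int = 512,
    max_shift_px: int = 40,
    jitter_px: float = 0.0,
    dropout: float = 0.0,
    seed: int | None = None,
    border_px: int = 45,
    min_spacing_px: float = 2.0,
) -> tuple[list[ROITable], GroundTruth]:
    """Per-day ROI tables with planted shifts, jitter and dropout.

    Day-1 centroids are uniform over the field away from the borders with a
    minimum pairwise spacing; day d centroids are day-1 plus that day's
    integer field shift plus per-neuron Gaussian jitter, and each neuron is
    independently dropped with probability ``dropout``.  Ground truth stores
    the shifts and the stable-id -> per-day ROI id map.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    usable = field_px - 2 * border_px
    if usable <= 0 or n_neurons * np.pi * (min_spacing_px / 2) ** 2 > usable**2:
        raise ValueError("too many neurons for the field at the minimum spacing")
    rng = np.random.default_rng(seed)

    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_neurons:
        cand = rng.uniform(border_px, field_px - border_px, 2)
        if all(np.hypot(*(cand - q)) >= min_spacing_px for q in pts):
            pts.append(cand)
        attempts += 1
        if attempts > 1000 * n_neurons:
            raise ValueError("could not place neurons at the minimum spacing")
    base = np.array(pts)

    shifts: list[tuple[int, int]] = [(0, 0)]
    for _ in range(n_days - 1):
        shifts.append(tuple(rng.integers(-max_shift_px, max_shift_px + 1, 2)))

    tables: list[ROITable] = []
    identity_map: dict = {}
    for day in range(n_days):
        dx, dy = shifts[day]
        xy = base + np.array([dx, dy], dtype=float)
        if jitter_px > 0 and day > 0:
            xy = xy + rng.normal(0, jitter_px, xy.shape)
        if day == 0:
            kept = np.arange(n_neurons)
        else:
            kept = np.nonzero(rng.random(n_neurons) >= dropout)[0]
        ids = np.arange(len(kept))
        tables.append(ROITable(day + 1, ids, xy[kept], field_px))
        identity_map[day + 1] = {int(stable): int(i) for i, stable in enumerate(kept)}

    truth = GroundTruth(day_shifts=shifts, identity_map=identity_map)
    return tables, truth
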