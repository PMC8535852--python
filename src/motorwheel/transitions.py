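"""Identification of neurons responsive to speed transitions.

A binary transition vector s marks the frames within a 15-s window after
each speed transition.  The similarity of a nonnegative calcium trace c to s
is the normalized inner product

    sim(c, s) = 2 (s . c) / (|s|^2 + |c|^2)

which lies in [0, 1]: it is 1 iff c equals s elementwise and 0 iff the two
vectors have disjoint support.  A per-neuron permutation null repositions the
transition windows at uniformly random onsets (circular wrap, window count
and lengths preserved); a neuron is "transition-active" when its observed
similarity exceeds the 99.95th percentile of its null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import TraceMatrix
from .profile import SpeedProfile

__all__ = [
    "TransitionVector",
    "SimilarityResult",
    "build_transition_vector",
    "similarity",
    "permutation_null",
    "classify_transition_active",
]


@dataclass
class TransitionVector:
    """Binary indicator of peri-transition frames."""

    values: np.ndarray
    window_s: float
    transition_frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_ones(self) -> int:
        return int(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SimilarityResult:
    """Per-neuron similarity, null threshold and transition-active flag."""

    similarity: np.ndarray
    threshold: np.ndarray
    active: np.ndarray
    percentile: float
    n_shuffles: int
    shuffle_mode: str

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def build_transition_vector(
    profile: SpeedProfile,
    frame_rate: float,
    window_s: float = 15.0,
    symmetric: bool = False,
) -> TransitionVector:
    """Mark the frames within ``window_s`` after each speed transition.

    With ``symmetric=True`` the window extends ``window_s`` on both sides of
    the transition.  Overlapping windows merge.
    """
    n = profile.n_frames(frame_rate)
    s = np.zeros(n)
    w = int(round(window_s * frame_rate))
    tf = profile.transition_frames(frame_rate)
    for f in tf:
        lo = max(0, f - w) if symmetric else f
        s[lo : min(n, f + w)] = 1.0
    return TransitionVector(s, window_s, tf, frame_rate)


def similarity(c: np.ndarray, s: np.ndarray | TransitionVector) -> float:
    """Normalized inner product 2(s.c)/(|s|^2 + |c|^2) of a trace and the
    transition vector.  The trace is clipped at zero first (ΔF/F)."""
    sv = s.values if isinstance(s, TransitionVector) else np.asarray(s, dtype=float)
    cv = np.clip(np.asarray(c, dtype=float), 0.0, None)
    if sv.shape != cv.shape:
        raise ValueError("trace and transition vector must have equal length")
    ss = float(sv @ sv)
    cc = float(cv @ cv)
    if ss + cc == 0:
        raise ValueError("similarity undefined when both vectors are all zero")
    return 2.0 * float(sv @ cv) / (ss + cc)


def _window_runs(s: np.ndarray) -> list[int]:
    """Lengths of the runs of ones in s (merged windows count once)."""
    a = np.r_[0, (s > 0).astype(np.int8), 0]
    edges = np.diff(a)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return list(ends - starts)


def _shuffled_vectors(
    s: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
    mode: str,
    max_tries: int = 100,
) -> np.ndarray:
    """(n_shuffles, T) matrix of shuffled transition vectors."""
    t = len(s)
    if mode == "elementwise":
        out = np.empty((n_shuffles, t), dtype=np.float32)
        for i in range(n_shuffles):
            out[i] = rng.permutation(s)
        return out
    if mode != "window":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    runs = _window_runs(s)
    if any(r > t for r in runs):
        raise ValueError("transition window longer than the recording")
    total = sum(runs)
    out = np.zeros((n_shuffles, t), dtype=np.float32)
    for i in range(n_shuffles):
        # reposition every window at a uniform random onset with circular
        # wrap; retry a few times to keep windows disjoint (preserves |s|^2)
        for _ in range(max_tries):
            row = np.zeros(t, dtype=np.float32)
            for length in runs:
                onset = int(rng.integers(t))
                idx = (onset + np.arange(length)) % t
                row[idx] = 1.0
            if row.sum() == total:
                break
        out[i] = row
    return out


def permutation_null(
    c: np.ndarray,
    s: np.ndarray | TransitionVector,
    n_shuffles: int = 5000,
    seed: int | None = None,
    mode: str = "window",
) -> np.ndarray:
    """Null similarity samples for one trace from shuffled transition vectors."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    sv = s.values if isinstance(s, TransitionVector) else np.asarray(s, dtype=float)
    cv = np.clip(np.asarray(c, dtype=float), 0.0, None)
    rng = np.random.default_rng(seed)
    shuf = _shuffled_vectors(sv, n_shuffles, rng, mode)
    cc = float(cv @ cv)
    ss = shuf.sum(axis=1)  # binary: |s|^2 = number of ones
    return 2.0 * (shuf @ cv) / (ss + cc)


def classify_transition_active(
    traces: TraceMatrix,
    profile: SpeedProfile,
    percentile: float = 99.95,
    n_shuffles: int = 5000,
    seed: int | None = None,
    window_s: float = 15.0,
    mode: str = "window",
) -> SimilarityResult:
    """Flag neurons whose similarity to the transition vector beats chance.

    One seeded shuffle ensemble is shared across neurons (each neuron is
    still thresholded against its own null similarity distribution, which
    depends on its trace norm).  A neuron is flagged iff its observed
    similarity strictly exceeds the ``percentile`` of its null samples.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    s = build_transition_vector(profile, traces.frame_rate, window_s)
    n_frames = len(s)
    if traces.n_frames < n_frames:
        raise ValueError("traces shorter than the speed profile")
    c = np.clip(traces.dff[:, :n_frames], 0.0, None)

    rng = np.random.default_rng(seed)
    shuf = _shuffled_vectors(s.values, n_shuffles, rng, mode)

    cc = np.einsum("ij,ij->i", c, c)  # per-neuron |c|^2
    ss_obs = float(s.values @ s.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = 2.0 * (c @ s.values) / (ss_obs + cc)
        null = 2.0 * (c @ shuf.T) / (shuf.sum(axis=1)[None, :] + cc[:, None])
    if percentile == 0:
        # degenerate threshold: the infimum of the similarity range, so any
        # neuron with nonzero similarity is flagged
        thresh = np.zeros(traces.n_neurons)
    else:
        thresh = np.percentile(null, percentile, axis=1)

    if ss_obs == 0:
        # no transitions: similarity is 0 for active neurons, undefined for
        # silent ones
        undef = cc == 0
        obs[undef] = np.nan
        thresh[undef] = np.nan
    active = np.nan_to_num(obs) > np.nan_to_num(thresh, nan=np.inf)
    return SimilarityResult(obs, thresh, active, percentile, n_shuffles, mode)
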