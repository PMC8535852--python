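"""Persistence of directly correlated neuron pairs across days.

Once neurons are tracked across sessions, each day's DCC matrix (over the
tracked id space) yields a set of "directly correlated" pairs via the
mean + 2 SD threshold on |DCC|.  For every pair ever detected, the number of
detection days is counted; the normalized histogram of those counts is the
persistence profile, and its excess (Fisher) kurtosis summarizes the shape
of the curve — a heavy concentration at one or two days gives a more peaked,
heavier-tailed distribution than a persistence spread over many days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PairwiseMatrix, strong_pairs

__all__ = [
    "PersistenceProfile",
    "detected_pairs_per_day",
    "persistence_histogram",
    "histogram_kurtosis",
]


@dataclass
class PersistenceProfile:
    """Detection-day counts of directly correlated pairs.

    ``histogram[k - 1]`` is the fraction of ever-detected pairs seen on
    exactly k days, k = 1..n_days.  Pairs never detected are excluded.
    """

    pair_days: dict
    n_days: int
    state: str | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pair_days)

    @property
    def histogram(self) -> np.ndarray:
        counts = np.bincount(
            list(self.pair_days.values()), minlength=self.n_days + 1
        )[1:]
        return counts / counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_detection_days": np.arange(1, self.n_days + 1), "fraction": self.histogram}
        )


def detected_pairs_per_day(
    dcc_by_day: list[PairwiseMatrix],
    pair_masks: list[np.ndarray] | None = None,
) -> list[set]:
    """Per-day sets of pairs passing the direct-correlation threshold.

    All matrices must share the tracked-neuron id space.  The threshold is
    the strong-pair rule (|DCC| > mean + 2 SD of the in-scope off-diagonal
    magnitudes), applied within each day.
    """
    sets: list[set] = []
    for day, mat in enumerate(dcc_by_day):
        if mat.n_neurons < 2:
            raise ValueError(f"day {day} has fewer than 2 tracked neurons")
        mask = pair_masks[day] if pair_masks is not None else None
        strong = strong_pairs(mat, mask)
        ii, jj = np.nonzero(strong)
        sets.append(
            {frozenset((int(mat.neuron_ids[i]), int(mat.neuron_ids[j]))) for i, j in zip(ii, jj)}
        )
    return sets


def persistence_histogram(
    pair_sets: list[set],
    n_days: int | None = None,
    state: str | None = None,
) -> PersistenceProfile:
    """Count detection days per ever-detected pair and normalize."""
    if n_days is None:
        n_days = len(pair_sets)
    if n_days < 1 or len(pair_sets) > n_days:
        raise ValueError("n_days must cover the supplied per-day sets")
    counts: dict = {}
    for s in pair_sets:
        for pair in s:
            counts[pair] = counts.get(pair, 0) + 1
    if not counts:
        raise ValueError("no directly correlated pairs detected on any day")
    return PersistenceProfile(counts, n_days, state)


def histogram_kurtosis(profile: PersistenceProfile | np.ndarray) -> float:
    """Excess (Fisher) kurtosis of the detection-day distribution.

    The histogram is treated as a weighted sample over its bin centers
    (counts 1..n_days); a single-bin distribution has no defined kurtosis.
    """
    if isinstance(profile, PersistenceProfile):
        w = profile.histogram
        x = np.arange(1, profile.n_days + 1, dtype=float)
    else:
        w = np.asarray(profile, dtype=float)
        x = np.arange(1, len(w) + 1, dtype=float)
    if w.sum() <= 0:
        raise ValueError("empty histogram")
    w = w / w.sum()
    if int((w > 0).sum()) < 2:
        raise ValueError("kurtosis undefined for a single-bin distribution")
    mu = float(w @ x)
    m2 = float(w @ (x - mu) ** 2)
    m4 = float(w @ (x - mu) ** 4)
    return m4 / m2**2 - 3.0
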