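"""Cross-day registration of imaged neurons.

The field of view drifts slightly between daily sessions, so the same neuron
appears at slightly different pixel coordinates.  Each session's detected
ROIs are rendered as an image: a sum of isotropic Gaussian peaks (height
1.0, SD 5 px, about the radius of a soma) on the 512 x 512 frame grid.  The
day-1 image is padded by the search half-width WS on every side and the
Pearson correlation of the two images is evaluated at every integer offset
in [-WS, WS]^2, a (2WS+1) x (2WS+1) score matrix whose argmax is the
field-of-view shift.  With WS = 40 the matrix is 81 x 81.  Given the shift,
neurons are matched one-to-one to the nearest shift-corrected candidate
within a 5-px tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import cdist

__all__ = [
    "ROITable",
    "ShiftResult",
    "RegistrationMap",
    "render_roi_image",
    "find_shift",
    "match_neurons",
    "track_across_days",
]

DEFAULT_FIELD_PX = 512
DEFAULT_WS = 40
DEFAULT_TOL_PX = 5.0
DEFAULT_SD_PX = 5.0


@dataclass
class ROITable:
    """Detected ROI centroids of one imaging session."""

    day: int
    ids: np.ndarray
    xy: np.ndarray  # (n, 2) pixel coordinates (x, y)
    field_px: int = DEFAULT_FIELD_PX

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.ids) != len(self.xy):
            raise ValueError("one id per centroid required")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("ROI ids must be unique within a day")

    @property
    def n_neurons(self) -> int:
        return len(self.ids)


@dataclass
class ShiftResult:
    """Field-of-view shift estimate and its full correlation-score matrix."""

    dx: int
    dy: int
    score: float
    score_matrix: np.ndarray

    @property
    def shift(self) -> tuple[int, int]:
        return (self.dx, self.dy)


@dataclass
class RegistrationMap:
    """Per-day shifts and the cross-day neuron identity correspondence.

    ``identity`` has one row per day-1 (reference) neuron and one column per
    day; entries are the matched ROI id on that day or NaN when absent.
    """

    shifts: list[tuple[int, int]]
    scores: list[float]
    identity: pd.DataFrame

    @property
    def n_days(self) -> int:
        return len(self.shifts)

    @property
    def fraction_tracked_all_days(self) -> float:
        return float(self.identity.notna().all(axis=1).mean())

    def tracked_days(self) -> pd.Series:
        """Number of days each reference neuron was found (including day 1)."""
        return self.identity.notna().sum(axis=1)


def render_roi_image(
    rois: ROITable,
    field_px: int | None = None,
    peak_height: float = 1.0,
    sd_px: float = DEFAULT_SD_PX,
) -> np.ndarray:
    """Render ROIs as a sum of Gaussian peaks on the imaging frame grid.

    Each neuron contributes an isotropic bivariate normal peak of maximum
    height ``peak_height`` and standard deviation ``sd_px`` centered at its
    pixel location; the image has the size of the raw frame.
    """
    if sd_px <= 0:
        raise ValueError("sd_px must be positive")
    size = int(field_px if field_px is not None else rois.field_px)
    img = np.zeros((size, size))
    half = int(np.ceil(4 * sd_px))
    for x, y in rois.xy:
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        xs = np.arange(max(0, x0), min(size, x1))
        ys = np.arange(max(0, y0), min(size, y1))
        if xs.size == 0 or ys.size == 0:
            continue
        gx = np.exp(-((xs - x) ** 2) / (2 * sd_px**2))
        gy = np.exp(-((ys - y) ** 2) / (2 * sd_px**2))
        img[np.ix_(ys, xs)] += peak_height * np.outer(gy, gx)
    return img


def find_shift(ref_image: np.ndarray, image: np.ndarray, ws: int = DEFAULT_WS) -> ShiftResult:
    """Exhaustive integer-offset search for the field-of-view shift.

    The reference is padded by ``ws`` on each side and the Pearson
    correlation of ``image`` with the matching window of the padded
    reference is computed at every offset in [-ws, ws]^2.  Returns the
    offset (dx, dy) maximizing the score — the translation taking the
    reference to ``image`` — and the (2 ws + 1)^2 score matrix indexed as
    ``score_matrix[dy + ws, dx + ws]``.  Ties break toward the smallest
    shift magnitude, then lexicographically on (dx, dy).
    """
    ref = np.asarray(ref_image, dtype=float)
    img = np.asarray(image, dtype=float)
    if ref.shape != img.shape or ref.ndim != 2:
        raise ValueError("images must be 2-D and of equal shape")
    if ws < 0 or ws >= min(ref.shape):
        raise ValueError("search half-width ws must satisfy 0 <= ws < image size")
    h, w = img.shape
    n = h * w
    padded = np.pad(ref, ws)

    # sliding dot products of img with every (h, w) window of the padded ref
    cross = signal.fftconvolve(padded, img[::-1, ::-1], mode="valid")
    # sliding window sums / sums of squares via integral images
    def _windowed_sum(a: np.ndarray) -> np.ndarray:
        c = np.cumsum(np.cumsum(np.pad(a, ((1, 0), (1, 0))), axis=0), axis=1)
        return c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]

    wsum = _windowed_sum(padded)
    wsum2 = _windowed_sum(padded**2)
    isum = img.sum()
    ivar = (img**2).sum() - isum**2 / n
    wvar = wsum2 - wsum**2 / n
    denom = np.sqrt(np.clip(wvar * ivar, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (cross - wsum * isum / n) / denom
    scores = np.nan_to_num(scores)

    # window at padded offset (i, j) contains ref[i - ws + y, j - ws + x]:
    # it matches image = ref translated by (dx, dy) when (i, j) = ws - (dy, dx)
    score_matrix = scores[::-1, ::-1]

    best = score_matrix.max()
    cand = np.argwhere(score_matrix >= best - 1e-12)
    offsets = cand - ws  # rows of (dy, dx)
    order = np.lexsort((offsets[:, 0], offsets[:, 1], (offsets**2).sum(axis=1)))
    dy, dx = offsets[order[0]]
    return ShiftResult(int(dx), int(dy), float(best), score_matrix)


def match_neurons(
    ref_rois: ROITable,
    rois: ROITable,
    shift: tuple[float, float],
    tol_px: float = DEFAULT_TOL_PX,
) -> dict:
    """Match reference neurons to shift-corrected candidates within tol_px.

    Candidate centroids are corrected by subtracting the field shift; each
    reference neuron takes the nearest candidate within ``tol_px`` (ties to
    the closest), each candidate is consumed at most once (greedy by
    ascending distance).  Returns ``{ref_id: matched_id}``; unmatched
    reference neurons are absent from the mapping.
    """
    if ref_rois.n_neurons == 0 or rois.n_neurons == 0:
        return {}
    corrected = rois.xy - np.asarray(shift, dtype=float)
    d = cdist(ref_rois.xy, corrected)
    ii, jj = np.nonzero(d <= tol_px)
    order = np.argsort(d[ii, jj], kind="stable")
    mapping: dict = {}
    used_ref: set[int] = set()
    used_cand: set[int] = set()
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_ref or j in used_cand:
            continue
        used_ref.add(i)
        used_cand.add(j)
        mapping[ref_rois.ids[i]] = rois.ids[j]
    return mapping


def track_across_days(
    tables: list[ROITable],
    ws: int = DEFAULT_WS,
    tol_px: float = DEFAULT_TOL_PX,
    sd_px: float = DEFAULT_SD_PX,
    field_px: int | None = None,
) -> RegistrationMap:
    """Register every session to day 1 and track neuron identities.

    Day 1 is the reference: each later day's ROI image is aligned by
    exhaustive shift search, then neurons are matched within ``tol_px``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 days to track")
    ref = tables[0]
    size = field_px if field_px is not None else ref.field_px
    ref_img = render_roi_image(ref, size, sd_px=sd_px)

    shifts: list[tuple[int, int]] = [(0, 0)]
    scores: list[float] = [1.0]
    columns = {f"day_{ref.day}": pd.Series(ref.ids, index=ref.ids)}
    for tab in tables[1:]:
        img = render_roi_image(tab, size, sd_px=sd_px)
        res = find_shift(ref_img, img, ws)
        shifts.append(res.shift)
        scores.append(res.score)
        mapping = match_neurons(ref, tab, res.shift, tol_px)
        columns[f"day_{tab.day}"] = pd.Series(
            [mapping.get(i, np.nan) for i in ref.ids], index=ref.ids
        )
    identity = pd.DataFrame(columns)
    identity.index.name = "ref_id"
    return RegistrationMap(shifts, scores, identity)
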