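"""Pairwise functional connectivity: Pearson and direct correlation (DCC).

Pearson correlation of two neurons' traces mixes direct coupling with shared
input along indirect paths.  The direct correlation coefficient removes the
indirect part under the maximum-entropy (Gaussian) model consistent with the
observed pairwise covariances: with precision matrix P = Sigma^-1,

    DCC_ij = -P_ij / sqrt(P_ii * P_jj)

i.e. the partial correlation of i and j conditional on every other recorded
neuron.  For a chain A-B-C this is exactly zero for the non-adjacent pair
even though their Pearson correlation is the product along the path.  A
shrinkage parameter lambda conditions the sample correlation matrix,
(1 - lambda) R + lambda I, which is required whenever the number of frames
does not comfortably exceed the number of neurons.

"Strong" pairs are those whose coefficient exceeds the mean plus two
standard deviations of all coefficients in scope (within L2/3, within L5a,
or across the two layers).  Proximity bias is summarized as the ratio of
mean |DCC| for pairs closer than 100 um to pairs between 100 and 200 um.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import TraceMatrix

__all__ = [
    "PairwiseMatrix",
    "pearson_matrix",
    "dcc_matrix",
    "scope_pair_mask",
    "strong_pairs",
    "mean_connectivity",
    "pair_table",
    "proximity_ratio",
]

logger = logging.getLogger(__name__)

SCOPES = ("all", "within", "cross")


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise connectivity over a set of neurons.

    ``kind`` is "pearson" (unit diagonal) or "dcc" (zero diagonal).
    ``neuron_ids`` maps matrix rows back to the caller's neuron indexing when
    zero-variance neurons were excluded.
    """

    values: np.ndarray
    kind: str
    neuron_ids: np.ndarray
    layer: np.ndarray | None = None
    block: slice | None = None

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def _block_data(traces: TraceMatrix, block: slice | None) -> np.ndarray:
    x = traces.dff if block is None else traces.dff[:, block]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 frames for a correlation")
    return x


def _drop_zero_variance(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.info("excluding %d zero-variance neurons", int((~keep).sum()))
    return x[keep], np.nonzero(keep)[0]


def pearson_matrix(traces: TraceMatrix, block: slice | None = None) -> PairwiseMatrix:
    """Pearson correlation between every pair of neurons over a frame block.

    Zero-variance neurons are excluded (and logged); at least two eligible
    neurons are required.
    """
    x, ids = _drop_zero_variance(_block_data(traces, block))
    if len(ids) < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance in block")
    r = np.corrcoef(x)
    layer = traces.layer[ids] if traces.layer is not None else None
    return PairwiseMatrix(r, "pearson", ids, layer, block)


def dcc_matrix(
    traces: TraceMatrix,
    block: slice | None = None,
    shrinkage: float = 0.05,
) -> PairwiseMatrix:
    """Direct correlation coefficients (partial correlations) over a block.

    The sample correlation matrix is shrunk toward the identity,
    ``(1 - shrinkage) R + shrinkage I`` (equivalent to shrinking the
    covariance toward its diagonal), then inverted; working on the
    correlation scale makes the result invariant to per-neuron affine
    rescaling of the traces.  At ``shrinkage = 1`` the precision is diagonal
    and every DCC is zero.
    """
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    x, ids = _drop_zero_variance(_block_data(traces, block))
    n = len(ids)
    if n < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance in block")
    if shrinkage == 0 and x.shape[1] <= n:
        raise ValueError(
            f"{x.shape[1]} frames for {n} neurons gives a singular correlation"
            " matrix; set shrinkage > 0"
        )
    r = np.corrcoef(x)
    rs = (1 - shrinkage) * r + shrinkage * np.eye(n)
    try:
        p = np.linalg.inv(rs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; increase the shrinkage parameter"
        ) from err
    d = np.sqrt(np.diag(p))
    dcc = -p / np.outer(d, d)
    np.fill_diagonal(dcc, 0.0)
    dcc = (dcc + dcc.T) / 2  # enforce exact symmetry
    layer = traces.layer[ids] if traces.layer is not None else None
    return PairwiseMatrix(dcc, "dcc", ids, layer, block)


def scope_pair_mask(matrix: PairwiseMatrix, scope: str = "all", layer: str | None = None) -> np.ndarray:
    """Boolean upper-triangle mask of the neuron pairs in a scope.

    ``scope`` is "all", "within" (both neurons in ``layer``) or "cross"
    (the two neurons in different layers).
    """
    n = matrix.n_neurons
    triu = np.triu(np.ones((n, n), dtype=bool), k=1)
    if scope == "all":
        return triu
    if matrix.layer is None:
        raise ValueError("scoped pair selection requires per-neuron layer labels")
    if scope == "within":
        if layer is None:
            raise ValueError('scope "within" requires a layer label')
        inlayer = matrix.layer == layer
        return triu & np.outer(inlayer, inlayer)
    if scope == "cross":
        return triu & (matrix.layer[:, None] != matrix.layer[None, :])
    raise ValueError(f"unknown scope {scope!r}")


def strong_pairs(matrix: PairwiseMatrix, pair_mask: np.ndarray | None = None) -> np.ndarray:
    """Pairs whose coefficient exceeds mean + 2 SD of the coefficients in scope.

    Pearson values are thresholded as signed coefficients; DCC values by
    magnitude.  Returns a boolean mask over the upper-triangle pairs in
    scope; with zero spread the set is empty (strict inequality).
    """
    if pair_mask is None:
        pair_mask = scope_pair_mask(matrix, "all")
    vals = matrix.values[pair_mask]
    if vals.size < 2:
        raise ValueError("need at least 2 off-diagonal values in scope")
    if matrix.kind == "dcc":
        vals = np.abs(vals)
    thresh = vals.mean() + 2 * vals.std()
    out = np.zeros_like(pair_mask)
    out[pair_mask] = vals > thresh
    return out


def mean_connectivity(
    matrix: PairwiseMatrix,
    pair_mask: np.ndarray | None = None,
    absolute: bool = True,
) -> float:
    """Mean (|)coefficient(|) over the pairs in scope."""
    if pair_mask is None:
        pair_mask = scope_pair_mask(matrix, "all")
    vals = matrix.values[pair_mask]
    if vals.size == 0:
        raise ValueError("no pairs in scope")
    return float(np.mean(np.abs(vals)) if absolute else np.mean(vals))


def pair_table(
    traces: TraceMatrix,
    block: slice | None = None,
    shrinkage: float = 0.05,
) -> pd.DataFrame:
    """One row per neuron pair: Pearson r, DCC, distance and strong flags.

    Distances are Euclidean centroid separations times the pixel size (um);
    NaN when the traces carry no centroid metadata.  Strong flags use the
    mean + 2 SD rule within each pair's own scope (within-layer or
    cross-layer) when layer labels exist, else over all pairs.
    """
    pm = pearson_matrix(traces, block)
    dm = dcc_matrix(traces, block, shrinkage)
    n = pm.n_neurons
    ids = pm.neuron_ids

    if traces.centroids is not None:
        xy = traces.centroids[ids]
        dist_px = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        dist = dist_px * (traces.pixel_size_um or 1.0)
    else:
        dist = np.full((n, n), np.nan)

    if pm.layer is not None:
        scopes = []
        for lab in np.unique(pm.layer):
            scopes.append((f"within-{lab}", scope_pair_mask(pm, "within", lab)))
        scopes.append(("cross-layer", scope_pair_mask(pm, "cross")))
    else:
        scopes = [("all", scope_pair_mask(pm, "all"))]

    rows = []
    for scope_name, mask in scopes:
        if not mask.any():
            continue
        strong_r = strong_pairs(pm, mask)
        strong_d = strong_pairs(dm, mask)
        ii, jj = np.nonzero(mask)
        for i, j in zip(ii, jj):
            rows.append(
                {
                    "neuron_i": int(ids[i]),
                    "neuron_j": int(ids[j]),
                    "scope": scope_name,
                    "r": pm.values[i, j],
                    "dcc": dm.values[i, j],
                    "distance_um": dist[i, j],
                    "strong_r": bool(strong_r[i, j]),
                    "strong_dcc": bool(strong_d[i, j]),
                }
            )
    return pd.DataFrame(rows)


def proximity_ratio(
    pairs: pd.DataFrame,
    near_max_um: float = 100.0,
    far_max_um: float = 200.0,
    value: str = "dcc",
) -> float:
    """Ratio of mean |DCC| for near pairs (< near_max_um) to intermediate
    pairs (near_max_um <= d < far_max_um): the DCC100/DCC200 proximity bias.

    Raises with the bin counts if either distance bin is empty.
    """
    d = pairs["distance_um"].to_numpy()
    v = np.abs(pairs[value].to_numpy())
    near = v[d < near_max_um]
    far = v[(d >= near_max_um) & (d < far_max_um)]
    if near.size == 0 or far.size == 0:
        raise ValueError(
            f"empty distance bin: {near.size} pairs < {near_max_um} um, "
            f"{far.size} pairs in [{near_max_um}, {far_max_um}) um"
        )
    return float(near.mean() / far.mean())
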