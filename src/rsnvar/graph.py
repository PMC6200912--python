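"""Edge weights, threshold sweep, and node strength for one network.

The edge weight between regions i and j is computed from the component
z-map as ``w_ij = |z_i| + |z_j| - |z_i - z_j|``; this equals
``2 * min(|z_i|, |z_j|)`` when the z-values share a sign and 0 when they
oppose.  Weights are normalized to [0, 1] by the matrix maximum (an
interpretive choice: the 0..1 threshold grid is meaningless on raw
z-derived weights), swept over the 101 thresholds 0, 0.01, ..., 1
(keeping entries >= threshold, averaging the thresholded copies), and
summed per row into node strengths.  Self-edges are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

N_THRESHOLDS = 101  # 0 to 1 in steps of 0.01


@dataclass
class EdgeWeightMatrix:
    """N x N symmetric nonnegative weights, zero diagonal."""

    w: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValidationError("edge weight matrix must be square")
        if not np.all(np.isfinite(self.w)):
            raise ValidationError("edge weights contain non-finite values")
        if not np.array_equal(self.w, self.w.T):
            raise ValidationError("edge weight matrix must be symmetric")
        if np.any(self.w < 0):
            raise ValidationError("edge weights must be nonnegative")
        if np.any(np.diag(self.w) != 0):
            raise ValidationError("edge weight diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return int(self.w.shape[0])


@dataclass
class GraphStrengthMap:
    """Per-region strength (row sums of effective weights)."""

    s: np.ndarray
    network: str = ""
    acquisition: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).ravel()
        if np.any(self.s < 0):
            raise ValidationError("graph strengths must be nonnegative")


def edge_weights(zmap: np.ndarray, normalize: bool = True) -> EdgeWeightMatrix:
    """Pairwise weights ``|z_i| + |z_j| - |z_i - z_j|`` with zero diagonal."""
    z = np.asarray(zmap, dtype=float).ravel()
    if z.size < 2:
        raise ValidationError("zmap needs at least 2 regions")
    if not np.all(np.isfinite(z)):
        raise ValidationError("zmap contains non-finite values")
    a = np.abs(z)
    w = a[:, None] + a[None, :] - np.abs(z[:, None] - z[None, :])
    np.fill_diagonal(w, 0.0)
    w = np.maximum(w, 0.0)  # clip float dust; exact result is >= 0
    wmax = w.max()
    if wmax == 0:
        warnings.warn("edge weight matrix is all zero", stacklevel=2)
        return EdgeWeightMatrix(w=w, normalized=normalize)
    if normalize:
        w = w / wmax
    return EdgeWeightMatrix(w=w, normalized=normalize)


def threshold_sweep(w: EdgeWeightMatrix) -> EdgeWeightMatrix:
    """Average of the 101 thresholded copies of a [0, 1] weight matrix.

    For a single weight ``w`` the average over thresholds t = k/100
    (keeping entries >= t) has the closed form
    ``w * (floor(100 w) + 1) / 101``.
    """
    if np.any(w.w > 1.0) or np.any(w.w < 0.0):
        raise ValidationError(
            "threshold sweep requires weights normalized to [0, 1]")
    surviving = np.floor(100.0 * w.w) + 1.0
    eff = w.w * surviving / N_THRESHOLDS
    np.fill_diagonal(eff, 0.0)
    return EdgeWeightMatrix(w=eff, normalized=False)


def strength(w_eff: EdgeWeightMatrix, network: str = "",
             acquisition: str = "") -> GraphStrengthMap:
    """Node strength: row sums of the (effective) weight matrix."""
    return GraphStrengthMap(s=w_eff.w.sum(axis=1), network=network,
                            acquisition=acquisition)


def network_strength_map(zmap: np.ndarray, network: str = "",
                         acquisition: str = "") -> GraphStrengthMap:
    """Convenience chain: edge weights -> normalize -> sweep -> strength."""
    w = edge_weights(zmap, normalize=True)
    return strength(threshold_sweep(w), network=network,
                    acquisition=acquisition)


def write_strength_map(gs: GraphStrengthMap, region_ids: np.ndarray,
                       path) -> None:
    pd.DataFrame({"region_id": np.asarray(region_ids, dtype=int),
                  "strength": gs.s}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
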