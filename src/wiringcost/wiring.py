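"""Inter-electrode distances and the wiring-cost matrix.

The wiring cost of a functional connectivity pattern is the connectivity
matrix weighted elementwise by the Euclidean distance between electrodes:

    W_ij = D_ij * F_ij

with D the straight-line distance (mm) between contact coordinates.  The
further apart two electrodes and the stronger their statistical coupling,
the larger the cost of "wiring" them — a proxy for the metabolic price of
the observed coupling pattern.  A network-level scalar is obtained by
summing W over the unordered pairs that carry an edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .connectivity import ConnectivityMatrix
from .datatypes import ElectrodeLayout

__all__ = ["WiringCostMatrix", "distance_matrix", "wiring_cost",
           "total_wiring_cost"]

logger = logging.getLogger(__name__)


@dataclass
class WiringCostMatrix:
    """W = D .* F, in mm x (connectivity units); symmetric, zero diagonal."""

    values: np.ndarray
    measure: str
    band: tuple
    channels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def distance_matrix(layout: ElectrodeLayout) -> np.ndarray:
    """Pairwise Euclidean distance matrix (mm) from contact coordinates.

    Duplicate coordinates (touching contacts) are permitted but logged.
    """
    if len(layout) < 2:
        raise ValueError("need at least 2 electrodes for a distance matrix")
    D = squareform(pdist(layout.coords))
    iu = np.triu_indices(len(layout), k=1)
    n_dup = int(np.sum(D[iu] == 0))
    if n_dup:
        logger.warning("distance_matrix: %d electrode pair(s) share coordinates", n_dup)
    return D


def wiring_cost(D: np.ndarray, F: ConnectivityMatrix,
                labels=None) -> WiringCostMatrix:
    """Elementwise product W = D .* F.

    ``labels``, when given, must equal the connectivity matrix's channel
    order — the function never reorders silently (use
    ``ElectrodeLayout.subset`` to align a layout first).

    Negative entries (anticorrelated pairs under the Spearman measure) are
    kept signed; the fraction of negative costs is logged.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != F.values.shape:
        raise ValueError(f"distance {D.shape} and connectivity {F.values.shape} "
                         "shapes differ")
    if labels is not None and list(labels) != list(F.channels):
        raise ValueError("label order mismatch between distance source and "
                         "connectivity matrix; align explicitly before weighting")
    W = D * F.values
    np.fill_diagonal(W, 0.0)
    frac_neg = float(np.mean(W[np.triu_indices(W.shape[0], k=1)] < 0)) if W.shape[0] > 1 else 0.0
    if frac_neg:
        logger.info("wiring_cost: %.1f%% of pair costs are negative", 100 * frac_neg)
    return WiringCostMatrix(values=W, measure=F.measure, band=F.band,
                            channels=list(F.channels))


def total_wiring_cost(W, adjacency: np.ndarray = None,
                      aggregate: str = "sum") -> float:
    """Network-level scalar wiring cost.

    Sums W_ij over unordered off-diagonal pairs (i < j).  With a binary
    ``adjacency``, only surviving edges contribute — the per-threshold
    wiring cost of a filtration step.  ``aggregate="mean"`` divides by the
    number of contributing pairs instead.
    """
    vals = W.values if isinstance(W, WiringCostMatrix) else np.asarray(W, dtype=float)
    n = vals.shape[0]
    iu = np.triu_indices(n, k=1)
    pair_vals = vals[iu]
    if adjacency is not None:
        mask = np.asarray(adjacency)[iu].astype(bool)
        pair_vals = pair_vals[mask]
    if pair_vals.size == 0:
        return 0.0
    if aggregate == "sum":
        return float(pair_vals.sum())
    if aggregate == "mean":
        return float(pair_vals.mean())
    raise ValueError(f"unknown aggregate {aggregate!r}")
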