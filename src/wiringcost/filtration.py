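"""Threshold filtration: network families swept over all thresholds.

Instead of committing to one arbitrary threshold, the filtration builds a
binary network at *every* value the weighted matrix takes: the threshold
vector T collects all off-diagonal values, and for each tau in T a binary
graph is formed.  Under the sublevel rule (edge iff value <= tau) the
family is nested — edges only appear as tau grows — running from the empty
graph below min(T) to the complete graph at max(T).  Four metrics are
tracked along the sweep: density, mean clustering, characteristic path
length (reachable pairs) and total wiring cost of the surviving edges.
Condition contrasts are step-function differences (eyes closed minus eyes
open) evaluated on the union threshold grid; because both conditions end in
the complete graph, the density and clustering differences always terminate
at exactly zero.

Note the two thresholding conventions coexist deliberately: the fixed
mean-plus-SD network keeps strong edges (superlevel), while the filtration
sweeps sublevel so that the family grows monotonically from empty to
complete.  Both rules are implemented and recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix
from .graph_metrics import binarize
from .wiring import WiringCostMatrix, total_wiring_cost

__all__ = ["FiltrationResult", "FILTRATION_METRICS", "build_threshold_vector",
           "filtrate", "filtration_difference", "evaluate_curves"]

FILTRATION_METRICS = ("clustering", "density", "char_path_length", "wiring_cost")

#: Metric values of the empty graph (the family's state below min(T)
#: under the sublevel rule).
_EMPTY = {"clustering": 0.0, "density": 0.0, "char_path_length": 0.0,
          "wiring_cost": 0.0}


@dataclass
class FiltrationResult:
    """Threshold vector plus per-threshold metric curves.

    ``thresholds`` is the sorted multiset of unique-pair values of the
    parent matrix; ``curves`` maps metric name -> array aligned with it.
    """

    thresholds: np.ndarray
    curves: dict
    rule: str = "sublevel"
    parent: str = ""
    n_channels: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be sorted ascending")


def build_threshold_vector(M, deduplicate: bool = False) -> np.ndarray:
    """Sorted vector of all off-diagonal values of a square matrix.

    Every value at which the thresholded network can change appears.  The
    upper-triangle multiset (n(n-1)/2 values) is used; including the
    symmetric halves would duplicate every value without changing the
    induced network family.  ``deduplicate`` collapses repeated values.
    """
    vals = M.offdiag() if hasattr(M, "offdiag") else _offdiag(np.asarray(M, float))
    if vals.size == 0:
        raise ValueError("need at least 2 channels")
    t = np.sort(vals)
    return np.unique(t) if deduplicate else t


def _offdiag(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def _graph_metrics_fast(adj: np.ndarray) -> dict:
    """Density, mean clustering, characteristic path length via array ops."""
    a = adj.astype(float)
    n = a.shape[0]
    n_pairs = n * (n - 1) / 2
    m = a.sum() / 2.0
    density = m / n_pairs if n_pairs else 0.0
    k = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0  # triangles through each node
    possible = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(possible > 0, tri / possible, 0.0)
    clustering = float(local.mean()) if n else 0.0
    if m == 0:
        return {"density": float(density), "clustering": 0.0,
                "char_path_length": 0.0}
    sp = shortest_path(a, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    d = sp[iu]
    finite = np.isfinite(d)
    cpl = float(d[finite].mean()) if finite.any() else 0.0
    return {"density": float(density), "clustering": clustering,
            "char_path_length": cpl}


def filtrate(M, D: np.ndarray = None, rule: str = "sublevel",
             deduplicate: bool = True) -> FiltrationResult:
    """Sweep all thresholds of ``M`` and track the four metric curves.

    Parameters
    ----------
    M : ConnectivityMatrix or WiringCostMatrix
        Matrix whose values define the edges.  Both are supported because
        the sweep can run on either the raw connectivity or the
        distance-weighted cost matrix; the choice is recorded in ``meta``.
    D : ndarray, optional
        Distance matrix.  Required when ``M`` is a connectivity matrix so
        the per-network wiring cost (sum of D_ij * F_ij over surviving
        edges) can be computed; ignored when ``M`` already is a wiring-cost
        matrix.
    rule : {"sublevel", "superlevel"}
        ``sublevel`` (edge iff value <= tau; nested, empty -> complete) is
        the default.
    deduplicate : bool
        Collapse repeated thresholds (the induced networks are identical);
        the full multiset is kept in ``meta["threshold_multiset_size"]``.
    """
    if rule not in ("sublevel", "superlevel"):
        raise ValueError(f"unknown rule {rule!r}")
    if isinstance(M, WiringCostMatrix):
        cost = M.values
        filtered_on = "wiring_cost"
    elif isinstance(M, ConnectivityMatrix):
        if D is None:
            raise ValueError("distance matrix D required to track wiring cost "
                             "when filtrating a connectivity matrix")
        if D.shape != M.values.shape:
            raise ValueError("distance/connectivity shape mismatch")
        cost = D * M.values
        filtered_on = "connectivity"
    else:
        raise TypeError("M must be a ConnectivityMatrix or WiringCostMatrix")

    full = build_threshold_vector(M, deduplicate=False)
    taus = np.unique(full) if deduplicate else full
    curves = {name: np.empty(taus.size) for name in FILTRATION_METRICS}
    for i, tau in enumerate(taus):
        adj = binarize(M.values, tau, rule)
        gm = _graph_metrics_fast(adj)
        for name in ("clustering", "density", "char_path_length"):
            curves[name][i] = gm[name]
        curves["wiring_cost"][i] = total_wiring_cost(cost, adjacency=adj)
    return FiltrationResult(
        thresholds=taus, curves=curves, rule=rule,
        parent=getattr(M, "measure", ""),
        n_channels=M.values.shape[0],
        meta={"filtered_on": filtered_on,
              "threshold_multiset_size": int(full.size)},
    )


def evaluate_curves(result: FiltrationResult, taus: np.ndarray) -> dict:
    """Evaluate the step-function curves at arbitrary thresholds.

    Under the sublevel rule the network at tau contains all edges with
    value <= tau, so each curve is a right-continuous step function of tau
    that changes only at stored thresholds; below min(T) the family is the
    empty graph.  Under the superlevel rule the roles reverse (empty above
    max(T)).
    """
    taus = np.asarray(taus, dtype=float)
    out = {}
    T = result.thresholds
    for name in FILTRATION_METRICS:
        vals = result.curves[name]
        if result.rule == "sublevel":
            idx = np.searchsorted(T, taus, side="right") - 1
            y = np.where(idx >= 0, vals[np.clip(idx, 0, len(T) - 1)], _EMPTY[name])
        else:
            idx = np.searchsorted(T, taus, side="left")
            y = np.where(idx < len(T), vals[np.clip(idx, 0, len(T) - 1)], _EMPTY[name])
        out[name] = y
    return out


def filtration_difference(f_ec: FiltrationResult, f_eo: FiltrationResult) -> dict:
    """Eyes-closed minus eyes-open metric curves on the union threshold grid.

    Both filtrations must use the same rule (and should come from the same
    measure); their threshold vectors may differ, so each step function is
    re-evaluated on the sorted union of the two grids before subtracting.

    Returns a dict with ``thresholds`` (the union grid) and one difference
    array per metric.  At the final grid point both families are complete
    under the sublevel rule, so the density and clustering differences end
    at exactly zero.
    """
    if f_ec.rule != f_eo.rule:
        raise ValueError(f"rule mismatch: {f_ec.rule} vs {f_eo.rule}")
    grid = np.union1d(f_ec.thresholds, f_eo.thresholds)
    ec = evaluate_curves(f_ec, grid)
    eo = evaluate_curves(f_eo, grid)
    out = {"thresholds": grid}
    for name in FILTRATION_METRICS:
        out[name] = ec[name] - eo[name]
    return out
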