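"""Fixed-threshold binary networks and the network-metric battery.

A weighted connectivity matrix is binarised at a fixed threshold equal to
the mean plus one standard deviation of its off-diagonal values (an edge
survives when its value is >= the threshold).  On the resulting undirected
binary graph a battery of 14 metrics is computed; per-subject differences
of these metrics between the eyes-closed and eyes-open conditions are the
unit of comparison across subjects, since heterogeneous implants make raw
per-subject networks incomparable.

Conventions for degenerate graphs (all values stay finite):

* characteristic path length averages geodesics over *reachable* pairs
  only (0 when no pair is reachable); the count of unreachable pairs is
  reported alongside;
* assortativity and core/periphery quality are 0 when the defining
  correlation is degenerate (e.g. regular or empty graphs);
* eigenvector centrality is computed on the largest component, zero
  elsewhere, normalised to unit maximum;
* modularity is that of the greedy modularity-maximising partition, 0 for
  an empty graph.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = ["BinaryNetwork", "METRIC_NAMES", "threshold_fixed", "binarize",
           "compute_metrics", "condition_difference"]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "gtom",                 # generalized topological overlap, mean over pairs
    "matching_index",       # mean over pairs
    "density",
    "clustering",           # mean local clustering coefficient
    "transitivity",
    "n_components",
    "largest_component",
    "modularity",           # Q of the greedy modularity partition
    "assortativity",        # degree assortativity
    "core_periphery",       # Borgatti-Everett-style quality
    "char_path_length",     # mean geodesic over reachable pairs
    "eigenvector_centrality",  # mean, normalised to unit max
    "pagerank",             # mean (damping 0.85)
    "degree",               # mean degree
)


@dataclass
class BinaryNetwork:
    """Undirected binary graph obtained by thresholding a weighted matrix.

    ``rule`` records how the threshold was applied: ``superlevel`` keeps an
    edge when the value is >= tau (the fixed-threshold convention),
    ``sublevel`` when the value is <= tau (the filtration convention).
    """

    adjacency: np.ndarray
    threshold: float
    rule: str = "superlevel"
    parent: str = ""
    channels: list = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        a = (a != 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if self.rule not in ("superlevel", "sublevel"):
            raise ValueError(f"unknown rule {self.rule!r}")
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.add_nodes_from(range(self.n))
        return g


def binarize(values: np.ndarray, tau: float, rule: str = "superlevel") -> np.ndarray:
    """0/1 adjacency from a weighted matrix at threshold ``tau``."""
    v = np.asarray(values, dtype=float)
    adj = (v >= tau) if rule == "superlevel" else (v <= tau)
    adj = adj.astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def threshold_fixed(F: ConnectivityMatrix) -> BinaryNetwork:
    """Binarise at tau = mean + population SD of the unique pair values.

    The superlevel rule is used: an edge survives iff F_ij >= tau.  For a
    zero-variance matrix tau reduces to the mean (complete graph under the
    >= rule); this is logged.
    """
    if F.n < 2:
        raise ValueError("need at least 2 channels")
    vals = F.offdiag()
    mu, sd = float(vals.mean()), float(vals.std())  # population SD (ddof=0)
    if sd == 0:
        logger.warning("threshold_fixed: zero-variance matrix, tau = mean")
    tau = mu + sd
    return BinaryNetwork(adjacency=binarize(F.values, tau, "superlevel"),
                         threshold=tau, rule="superlevel",
                         parent=F.measure, channels=list(F.channels))


def _pair_iter(n):
    return itertools.combinations(range(n), 2)


def _gtom_mean(a: np.ndarray) -> float:
    """Generalized topological overlap (one-step), averaged over pairs."""
    n = a.shape[0]
    if n < 2:
        return 0.0
    shared = a @ a  # number of shared neighbours
    k = a.sum(axis=1)
    total = 0.0
    for i, j in _pair_iter(n):
        denom = min(k[i], k[j]) + 1 - a[i, j]
        total += (shared[i, j] + a[i, j]) / denom if denom > 0 else 0.0
    return total / (n * (n - 1) / 2)


def _matching_index_mean(a: np.ndarray) -> float:
    """Matching index: shared / total distinct neighbours (excluding i, j)."""
    n = a.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i, j in _pair_iter(n):
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        ni, nj = a[i] & mask.astype(np.int8), a[j] & mask.astype(np.int8)
        union = int(np.sum(ni | nj))
        total += int(np.sum(ni & nj)) / union if union > 0 else 0.0
    return total / (n * (n - 1) / 2)


def _char_path_length(g: nx.Graph) -> tuple:
    """(mean geodesic over reachable pairs, number of unreachable pairs)."""
    n = g.number_of_nodes()
    n_pairs = n * (n - 1) // 2
    total, reachable = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            reachable += len(dists) - 1
    reachable //= 2
    total /= 2.0
    cpl = total / reachable if reachable else 0.0
    return cpl, n_pairs - reachable


def _assortativity(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = nx.degree_assortativity_coefficient(g)
    return 0.0 if not np.isfinite(r) else float(r)


def _core_periphery(a: np.ndarray) -> float:
    """Borgatti–Everett-style quality with deterministic initialisation.

    Core = nodes of degree >= mean degree; quality = Pearson correlation
    between the off-diagonal adjacency and the ideal core/periphery pattern
    (1 when either endpoint is in the core).  0 when degenerate.
    """
    n = a.shape[0]
    if n < 2:
        return 0.0
    k = a.sum(axis=1)
    if k.sum() == 0:
        return 0.0
    core = k >= k.mean()
    iu = np.triu_indices(n, k=1)
    ideal = (core[:, None] | core[None, :])[iu].astype(float)
    obs = a[iu].astype(float)
    if obs.std() == 0 or ideal.std() == 0:
        return 0.0
    return float(np.corrcoef(obs, ideal)[0, 1])


def _eigenvector_centrality_mean(a: np.ndarray, g: nx.Graph) -> float:
    n = a.shape[0]
    if g.number_of_edges() == 0:
        return 0.0
    comp = max(nx.connected_components(g), key=len)
    idx = sorted(comp)
    sub = a[np.ix_(idx, idx)].astype(float)
    w, v = np.linalg.eigh(sub)
    lead = np.abs(v[:, np.argmax(w)])
    cent = np.zeros(n)
    cent[idx] = lead
    mx = cent.max()
    if mx > 0:
        cent /= mx
    return float(cent.mean())


def compute_metrics(B: BinaryNetwork) -> dict:
    """All 14 battery metrics plus the unreachable-pair count.

    Per-node metrics (degree, centralities, matching index, topological
    overlap) are averaged over nodes/pairs so every metric is a single
    per-network scalar.
    """
    a = B.adjacency
    g = B.graph()
    n = B.n
    cpl, unreachable = _char_path_length(g)
    if g.number_of_edges() > 0:
        communities = nx.community.greedy_modularity_communities(g)
        modularity = float(nx.community.modularity(g, communities))
    else:
        modularity = 0.0
    pagerank = nx.pagerank(g, alpha=0.85, tol=1e-9, max_iter=1000)
    components = list(nx.connected_components(g))
    return {
        "gtom": _gtom_mean(a),
        "matching_index": _matching_index_mean(a),
        "density": float(nx.density(g)),
        "clustering": float(nx.average_clustering(g)) if n else 0.0,
        "transitivity": float(nx.transitivity(g)),
        "n_components": float(len(components)),
        "largest_component": float(max(len(c) for c in components)) if components else 0.0,
        "modularity": modularity,
        "assortativity": _assortativity(g),
        "core_periphery": _core_periphery(a),
        "char_path_length": cpl,
        "eigenvector_centrality": _eigenvector_centrality_mean(a, g),
        "pagerank": float(np.mean(list(pagerank.values()))) if n else 0.0,
        "degree": float(a.sum(axis=1).mean()) if n else 0.0,
        "unreachable_pairs": float(unreachable),
    }


def condition_difference(m_ec: dict, m_eo: dict) -> dict:
    """Per-metric signed difference, eyes closed minus eyes open.

    A positive value means the metric is larger with eyes closed (plotted
    blue in the battery figure convention); negative means larger with eyes
    open (red).
    """
    if set(m_ec) != set(m_eo):
        raise ValueError("metric name mismatch between conditions")
    return {k: m_ec[k] - m_eo[k] for k in m_ec}
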