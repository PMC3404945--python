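"""Global and nodal graph metrics with degree-matched random null models.

Small-worldness follows the usual normalization: sigma = (C/C_rand) /
(L/L_rand), where C_rand and L_rand are ensemble means over random graphs
with the same degree sequence as the graph of interest, obtained by
Maslov-Sneppen double-edge-swap rewiring.

Path length on fragmented graphs is averaged over same-component pairs by
default ("component" mode); "harmonic" mode instead returns the reciprocal of
the mean inverse distance, where disconnected pairs contribute zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryGraph

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "RandomEnsemble",
    "clustering_coefficient",
    "characteristic_path_length",
    "generate_random_ensemble",
    "small_worldness",
    "betweenness_and_degree",
    "identify_hubs",
]

PATH_LENGTH_MODES = ("component", "harmonic")


@dataclass(frozen=True)
class GlobalMetrics:
    """Small-world summary of one graph against its random ensemble."""

    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    gamma: float
    lam: float
    sigma: float
    ensemble_size: int


@dataclass
class NodalMetrics:
    """Per-node degree, normalized betweenness, and hub flags."""

    roi_labels: list[str]
    degree: np.ndarray
    betweenness: np.ndarray
    is_hub: np.ndarray

    def hub_labels(self) -> set[str]:
        return {label for label, flag in zip(self.roi_labels, self.is_hub) if flag}


@dataclass
class RandomEnsemble:
    """Degree-preserving rewired null graphs for one reference graph."""

    members: list[BinaryGraph]
    iterations_per_edge: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.members)


def clustering_coefficient(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering (0 for degree < 2) and its unweighted mean."""
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    triangles = (a @ a * a).sum(axis=1) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nodal = np.where(possible > 0, triangles / np.where(possible > 0, possible, 1.0), 0.0)
    return nodal, float(nodal.mean())


def _hop_distances(g: BinaryGraph) -> np.ndarray:
    return shortest_path(csr_matrix(g.adjacency), method="D", unweighted=True)


def characteristic_path_length(g: BinaryGraph, mode: str = "component") -> float:
    """Mean shortest-path hop count between node pairs.

    mode="component": average over pairs in the same connected component
    (classical value on a connected graph).  mode="harmonic": reciprocal of
    the mean inverse distance over all pairs (disconnected pairs count 0).
    """
    if mode not in PATH_LENGTH_MODES:
        raise ValueError(f"unknown path_length mode {mode!r}")
    if g.edge_count == 0:
        raise ValueError("characteristic path length is undefined on an empty graph")
    dist = _hop_distances(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    if mode == "component":
        reachable = np.isfinite(dist) & off
        return float(dist[reachable].mean())
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & off
    inv[finite] = 1.0 / dist[finite]
    return float(1.0 / inv[off].mean())


def generate_random_ensemble(
    g: BinaryGraph,
    size: int,
    iterations_per_edge: int = 10,
    seed: int | None = None,
) -> RandomEnsemble:
    """Degree-preserving double-edge-swap null ensemble.

    Each member starts from ``g`` and undergoes ``iterations_per_edge * E``
    swap attempts.  Graphs admitting no legal swap (e.g. a triangle) are
    returned unrewired with a warning.
    """
    if size < 1:
        raise ValueError("ensemble size must be positive")
    rng = np.random.default_rng(seed)
    n_swaps = iterations_per_edge * g.edge_count
    members: list[BinaryGraph] = []
    warned = False
    for _ in range(size):
        graph = g.to_networkx()
        member_seed = int(rng.integers(0, 2**32))
        try:
            nx.double_edge_swap(
                graph, nswap=n_swaps, max_tries=100 * n_swaps + 100, seed=member_seed
            )
        except nx.NetworkXError:
            if not warned:
                warnings.warn(
                    "no legal degree-preserving swap exists; ensemble members "
                    "are copies of the input graph",
                    stacklevel=2,
                )
                warned = True
        adjacency = nx.to_numpy_array(graph, nodelist=g.roi_labels, dtype=np.int8)
        members.append(BinaryGraph(roi_labels=list(g.roi_labels), adjacency=adjacency))
    return RandomEnsemble(members=members, iterations_per_edge=iterations_per_edge, seed=seed)


def small_worldness(
    g: BinaryGraph,
    ensemble: RandomEnsemble,
    path_length_mode: str = "component",
) -> GlobalMetrics:
    """gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    _, c_obs = clustering_coefficient(g)
    l_obs = characteristic_path_length(g, mode=path_length_mode)
    c_rand = float(
        np.mean([clustering_coefficient(m)[1] for m in ensemble.members])
    )
    l_rand = float(
        np.mean(
            [characteristic_path_length(m, mode=path_length_mode) for m in ensemble.members]
        )
    )
    if c_rand == 0.0:
        raise ValueError("degenerate null: ensemble mean clustering is zero")
    gamma = c_obs / c_rand
    lam = l_obs / l_rand
    return GlobalMetrics(
        clustering=c_obs,
        path_length=l_obs,
        clustering_rand=c_rand,
        path_length_rand=l_rand,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        ensemble_size=len(ensemble),
    )


def betweenness_and_degree(g: BinaryGraph) -> NodalMetrics:
    """Exact Brandes betweenness normalized to [0, 1], plus degrees and hubs."""
    centrality = nx.betweenness_centrality(g.to_networkx(), normalized=True)
    betweenness = np.array([centrality[label] for label in g.roi_labels])
    nodal = NodalMetrics(
        roi_labels=list(g.roi_labels),
        degree=g.degrees,
        betweenness=betweenness,
        is_hub=np.zeros(g.n_nodes, dtype=bool),
    )
    hubs = identify_hubs(nodal)
    nodal.is_hub = np.array([label in hubs for label in g.roi_labels])
    return nodal


def identify_hubs(nodal: NodalMetrics) -> set[str]:
    """Nodes whose betweenness is >= mean + 2 population SD (none if SD = 0)."""
    b = nodal.betweenness
    sd = float(b.std())
    if sd == 0.0:
        return set()
    cut = float(b.mean()) + 2.0 * sd
    return {label for label, value in zip(nodal.roi_labels, b) if value >= cut}
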