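"""Independent brute-force graph-metric implementations used as test oracles.

These deliberately avoid the package's code paths (and networkx): clustering
by explicit neighbor-pair enumeration, distances by Floyd-Warshall over hops,
betweenness by enumerating every shortest path.  Only usable for small N.
"""

import itertools

import numpy as np


def brute_clustering(adjacency):
    n = adjacency.shape[0]
    values = np.zeros(n)
    for i in range(n):
        neighbors = [j for j in range(n) if adjacency[i, j]]
        k = len(neighbors)
        if k < 2:
            continue
        links = sum(
            adjacency[a, b] for a, b in itertools.combinations(neighbors, 2)
        )
        values[i] = links / (k * (k - 1) / 2)
    return values, values.mean()


def brute_distances(adjacency):
    n = adjacency.shape[0]
    dist = np.where(adjacency > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_path_length(adjacency, mode="component"):
    dist = brute_distances(adjacency)
    n = adjacency.shape[0]
    off = ~np.eye(n, dtype=bool)
    if mode == "component":
        finite = np.isfinite(dist) & off
        return dist[finite].mean()
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & off
    inv[finite] = 1.0 / dist[finite]
    return 1.0 / inv[off].mean()


def _all_shortest_paths(adjacency, source, target, dist):
    """Enumerate every shortest path from source to target."""
    if not np.isfinite(dist[source, target]):
        return []
    if source == target:
        return [[source]]
    paths = []
    stack = [[source]]
    while stack:
        path = stack.pop()
        last = path[-1]
        if last == target:
            paths.append(path)
            continue
        for nxt in np.nonzero(adjacency[last])[0]:
            if dist[source, nxt] == len(path) and dist[nxt, target] == dist[
                source, target
            ] - len(path):
                stack.append(path + [int(nxt)])
    return paths


def brute_betweenness(adjacency):
    """Normalized betweenness: fraction of shortest paths through each node."""
    n = adjacency.shape[0]
    dist = brute_distances(adjacency)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adjacency, s, t, dist)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


def brute_hubs(betweenness, labels):
    sd = betweenness.std()
    if sd == 0:
        return set()
    cut = betweenness.mean() + 2 * sd
    return {lab for lab, b in zip(labels, betweenness) if b >= cut}
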