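"""Association matrices and density-thresholded binary graphs.

The association matrix holds the Pearson correlation, across subjects, of the
residual volumes of every pair of regions.  Binarization keeps the E largest
signed correlations, where E = round(density * N(N-1)/2); density 1 yields
the complete graph.  Ties at the cutoff are broken by (row, column)
lexicographic order of the edge so that thresholding is deterministic and the
edge sets at increasing densities are nested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .preprocess import ResidualTable
from .synthetic import SubjectVolumeTable

__all__ = [
    "AssociationMatrix",
    "BinaryGraph",
    "DensityGrid",
    "build_association_matrix",
    "threshold_at_density",
    "min_full_connectivity_density",
    "association_summary",
]


@dataclass
class AssociationMatrix:
    """Symmetric N x N Pearson matrix with a zeroed diagonal."""

    roi_labels: list[str]
    values: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError("association matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("association matrix diagonal must be zero")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1.0 - 1e-12 or off.max() > 1.0 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def n_pairs(self) -> int:
        n = self.n_rois
        return n * (n - 1) // 2


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    roi_labels: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.roi_labels)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match labels")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not ((self.adjacency == 0) | (self.adjacency == 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = self.adjacency.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.roi_labels)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.edge_count / (n * (n - 1) / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def is_connected(self) -> bool:
        return _is_connected(self.adjacency)

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(self.roi_labels)
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        graph.add_edges_from(
            (self.roi_labels[a], self.roi_labels[b]) for a, b in zip(i, j)
        )
        return graph

    def edge_list(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.roi_labels[a], self.roi_labels[b]) for a, b in zip(i, j)]


@dataclass(frozen=True)
class DensityGrid:
    """Strictly increasing sweep of target densities in (0, 1]."""

    densities: tuple[float, ...]
    step: float = field(default=0.0)

    def __post_init__(self) -> None:
        dens = tuple(float(d) for d in self.densities)
        if not dens:
            raise ValueError("density grid is empty")
        if any(not 0.0 < d <= 1.0 for d in dens):
            raise ValueError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(dens, dens[1:])):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "densities", dens)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "DensityGrid":
        count = int(round((stop - start) / step)) + 1
        dens = tuple(round(start + i * step, 10) for i in range(count))
        return cls(densities=dens, step=step)

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)


def build_association_matrix(
    residuals: ResidualTable | SubjectVolumeTable,
) -> AssociationMatrix:
    """Pearson correlation of every ROI pair across subjects, diagonal zeroed."""
    if residuals.n_subjects < 3:
        raise ValueError("need at least 3 subjects to correlate")
    stds = residuals.volumes.std(axis=0)
    zero = np.flatnonzero(stds == 0)
    if zero.size:
        names = ", ".join(residuals.roi_labels[i] for i in zero[:5])
        raise ValueError(f"zero-variance ROI column(s): {names}")
    corr = np.corrcoef(residuals.volumes, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return AssociationMatrix(
        roi_labels=list(residuals.roi_labels),
        values=corr,
        n_subjects=residuals.n_subjects,
    )


_triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _triu_cache:
        _triu_cache[n] = np.triu_indices(n, 1)
    return _triu_cache[n]


def ranked_edges(assoc: AssociationMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending r, ties by (i, j) order."""
    iu, ju = _triu_indices(assoc.n_rois)
    vals = assoc.values[iu, ju]
    # stable sort on -r: ties keep row-major (i, j) upper-triangle order
    order = np.argsort(-vals, kind="stable")
    return iu[order], ju[order], vals[order]


def edge_count_for_density(density: float, n: int) -> int:
    """E = round(D * N(N-1)/2) with symmetric half-up rounding."""
    m = n * (n - 1) // 2
    return int(np.floor(density * m + 0.5))


def threshold_at_density(assoc: AssociationMatrix, density: float) -> BinaryGraph:
    """Keep the E largest signed correlations; E = round(density * N(N-1)/2)."""
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    n = assoc.n_rois
    m = assoc.n_pairs
    n_edges = min(edge_count_for_density(density, n), m)
    if n_edges == 0:
        raise ValueError(
            f"density {density} yields zero edges for {n} nodes"
        )
    i, j, vals = ranked_edges(assoc)
    if vals[n_edges - 1] <= 0.0:
        warnings.warn(
            f"correlation cutoff at density {density} is non-positive "
            f"({vals[n_edges - 1]:.4f}); negative correlations enter the graph",
            stacklevel=2,
        )
    adjacency = np.zeros((n, n), dtype=np.int8)
    adjacency[i[:n_edges], j[:n_edges]] = 1
    adjacency |= adjacency.T
    return BinaryGraph(roi_labels=list(assoc.roi_labels), adjacency=adjacency)


class _UnionFind:
    __slots__ = ("parent", "size", "n_components")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_components -= 1


def _connected_with_top_k(i: np.ndarray, j: np.ndarray, n: int, k: int) -> bool:
    uf = _UnionFind(n)
    for a, b in zip(i[:k].tolist(), j[:k].tolist()):
        uf.union(a, b)
    return uf.n_components == 1


def _min_connecting_edge_count(assoc: AssociationMatrix) -> int:
    i, j, _ = ranked_edges(assoc)
    n = assoc.n_rois
    lo, hi = n - 1, assoc.n_pairs
    if not _connected_with_top_k(i, j, n, hi):  # defensive; complete graph connects
        raise ValueError("association matrix cannot produce a connected graph")
    # Edge sets are nested in k, so connectivity is monotone: binary search.
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected_with_top_k(i, j, n, mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def min_full_connectivity_density(assocs: list[AssociationMatrix]) -> float:
    """Smallest grid density k/(N(N-1)/2) connecting every input network.

    Per matrix this is the percolation point of the top-k edge filtration;
    the result is the maximum over matrices.
    """
    if not assocs:
        raise ValueError("need at least one association matrix")
    n = assocs[0].n_rois
    if any(a.n_rois != n for a in assocs):
        raise ValueError("association matrices differ in size")
    k_star = max(_min_connecting_edge_count(a) for a in assocs)
    return k_star / (n * (n - 1) / 2)


def association_summary(assoc: AssociationMatrix) -> np.ndarray:
    """Upper-triangle off-diagonal correlations in row-major order."""
    iu, ju = _triu_indices(assoc.n_rois)
    return assoc.values[iu, ju].copy()


def _is_connected(adjacency: np.ndarray) -> bool:
    n = adjacency.shape[0]
    if n == 0:
        return True
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    n_comp, _ = connected_components(csr_matrix(adjacency), directed=False)
    return n_comp == 1
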