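"""Zone adjacency graphs and the precision matrices of the spatial / smooth priors.

The structured spatial prior is an intrinsic conditional autoregressive (ICAR)
Gaussian Markov random field over the zone adjacency graph, with precision

    Q = D - A,   Q[d,d] = n_d (number of neighbours),  Q[d,e] = -1 for d ~ e.

Q is symmetric, has zero row sums, is positive semidefinite, and is rank
deficient: its nullspace is spanned by the per-connected-component constant
vectors, so rank(Q) = n_zones - #components.  The full conditional of one
zone given the rest is N(mean of neighbours, tau^2 / n_d).

Nonlinear covariate effects use a second-order random-walk (RW2) prior on a
sequence of bin effects; its structure matrix K = D2' D2 (D2 the second
difference operator) penalises squared second differences and has a
two-dimensional nullspace of constant and linear sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "adjacency_from_polygons",
    "icar_precision",
    "rw2_precision",
    "conditional_moments",
    "PrecisionMatrix",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected graph over zones 0..n_zones-1 with shared-boundary edges."""

    n_zones: int
    edges: frozenset  # frozenset of frozenset({a, b}) pairs

    def __post_init__(self) -> None:
        if self.n_zones < 1:
            raise ValueError("graph needs at least one zone")
        for e in self.edges:
            a, b = tuple(e)
            if a == b:
                raise ValueError(f"self-loop at zone {a}")
            for z in (a, b):
                if not (0 <= z < self.n_zones):
                    raise ValueError(f"unknown zone id {z} (n_zones={self.n_zones})")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_array(self) -> np.ndarray:
        """(n_edges, 2) sorted array of zone-id pairs, a < b."""
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        arr = np.array(sorted(tuple(sorted(e)) for e in self.edges), dtype=int)
        return arr

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_zones, dtype=int)
        for e in self.edges:
            a, b = tuple(e)
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self, zone: int) -> list[int]:
        out = []
        for e in self.edges:
            a, b = tuple(e)
            if a == zone:
                out.append(b)
            elif b == zone:
                out.append(a)
        return sorted(out)

    def adjacency_matrix(self) -> sp.csr_matrix:
        arr = self.edge_array()
        data = np.ones(2 * len(arr))
        rows = np.concatenate([arr[:, 0], arr[:, 1]])
        cols = np.concatenate([arr[:, 1], arr[:, 0]])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_zones, self.n_zones))

    def components(self) -> tuple[int, np.ndarray]:
        """(number of connected components, component label per zone)."""
        if self.n_zones == 1:
            return 1, np.zeros(1, dtype=int)
        n, labels = connected_components(self.adjacency_matrix(), directed=False)
        return int(n), labels

    def to_edge_csv(self, path=None) -> str | None:
        df = pd.DataFrame(self.edge_array(), columns=["zone_a", "zone_b"])
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path, index=False)
        return None


def build_adjacency(
    edges: Iterable[tuple[int, int]] | str | pd.DataFrame,
    n_zones: int | None = None,
) -> AdjacencyGraph:
    """Build a graph from an edge list (pairs, a CSV path, or a DataFrame).

    Duplicate and reversed edges are collapsed to one undirected edge.  Zone
    ids must be contiguous 0..n-1; ``n_zones`` may exceed the largest id seen
    (isolated zones are allowed).
    """
    if isinstance(edges, str):
        edges = pd.read_csv(edges)
    if isinstance(edges, pd.DataFrame):
        edges = list(zip(edges.iloc[:, 0].astype(int), edges.iloc[:, 1].astype(int)))
    pairs = set()
    max_id = -1
    for a, b in edges:
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-loop at zone {a}")
        if a < 0 or b < 0:
            raise ValueError(f"negative zone id in edge ({a}, {b})")
        pairs.add(frozenset((a, b)))
        max_id = max(max_id, a, b)
    if n_zones is None:
        n_zones = max_id + 1
    if max_id >= n_zones:
        raise ValueError(f"unknown zone id {max_id} (n_zones={n_zones})")
    return AdjacencyGraph(n_zones=n_zones, edges=frozenset(pairs))


def adjacency_from_polygons(features, zone_id_property: str = "zone_id") -> AdjacencyGraph:
    """Shared-boundary (rook) adjacency from zone polygons.

    ``features`` is a GeoJSON FeatureCollection dict (or its feature list).
    Two zones are adjacent when their boundaries share a segment of positive
    length; a single shared corner point does not count.
    """
    from shapely.geometry import shape  # optional heavy import

    if isinstance(features, dict):
        features = features["features"]
    polys = {}
    for feat in features:
        zid = int(feat["properties"][zone_id_property])
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for zone {zid}")
        polys[zid] = geom
    ids = sorted(polys)
    if ids != list(range(len(ids))):
        raise ValueError(f"zone ids must be contiguous 0..n-1, got {ids}")
    edges = []
    for i in ids:
        for j in ids:
            if j <= i:
                continue
            inter = polys[i].boundary.intersection(polys[j].boundary)
            if inter.length > 0:
                edges.append((i, j))
    return build_adjacency(edges, n_zones=len(ids))


@dataclass
class PrecisionMatrix:
    """Sparse symmetric PSD structure matrix with its spectral metadata.

    The matrix is the *structure* part only; the model scales it by the
    inverse of a variance component (pi^2_str for ICAR, tau^2 for RW2).
    """

    matrix: sp.csr_matrix
    scale_role: str  # 'icar' or 'rw2'
    rank: int = field(init=False)
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)
    rank_tol: float = 1e-8

    def __post_init__(self) -> None:
        dense = self.matrix.toarray()
        if not np.allclose(dense, dense.T):
            raise ValueError("precision structure matrix must be symmetric")
        vals, vecs = np.linalg.eigh(dense)
        top = max(vals.max(), 1.0)
        if vals.min() < -self.rank_tol * top:
            raise ValueError("precision structure matrix must be PSD")
        vals = np.clip(vals, 0.0, None)
        self.eigenvalues = vals
        self.eigenvectors = vecs
        self.rank = int(np.sum(vals > self.rank_tol * top))

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def positive_eigenpairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues > tol and their eigenvectors (columns)."""
        top = max(self.eigenvalues.max(), 1.0)
        keep = self.eigenvalues > self.rank_tol * top
        return self.eigenvalues[keep], self.eigenvectors[:, keep]

    def to_coo_text(self, path=None) -> str | None:
        coo = self.matrix.tocoo()
        df = pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data})
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path, index=False)
        return None


def icar_precision(graph: AdjacencyGraph) -> PrecisionMatrix:
    """Intrinsic CAR structure matrix Q = D - A for a zone graph."""
    A = graph.adjacency_matrix()
    deg = np.asarray(A.sum(axis=1)).ravel()
    Q = sp.diags(deg) - A
    return PrecisionMatrix(matrix=sp.csr_matrix(Q), scale_role="icar")


def rw2_precision(m: int) -> PrecisionMatrix:
    """RW2 structure matrix K = D2' D2 on a length-m sequence of bin effects."""
    if m < 3:
        raise ValueError("RW2 needs at least 3 bins")
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
    K = (d2.T @ d2).tocsr()
    return PrecisionMatrix(matrix=K, scale_role="rw2")


def conditional_moments(
    Q: PrecisionMatrix,
    tau2: float,
    zone: int,
    neighbor_values: Sequence[float],
) -> tuple[float, float]:
    """Full-conditional mean and variance of one zone's ICAR effect.

    Given the effects of the zone's neighbours, the intrinsic prior implies
    mean = average of neighbour values and variance = tau2 / n_d.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    n_d = Q.matrix[zone, zone]
    if n_d == 0:
        raise ValueError(f"zone {zone} is isolated; its conditional is undefined")
    vals = np.asarray(neighbor_values, dtype=float)
    if len(vals) != int(n_d):
        raise ValueError(f"zone {zone} has {int(n_d)} neighbours, got {len(vals)} values")
    return float(vals.mean()), float(tau2 / n_d)
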