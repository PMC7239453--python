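"""Areal adjacency structure and boundary-crossing distances.

The models and smoothing diagnostics in this package all operate on a set of
areas linked by binary, first-order adjacency weights ``w_ij`` (1 if areas i
and j share a boundary, 0 otherwise).  This module builds that structure from
the common plain-text exchange formats (GAL neighbour lists, two-column edge
lists, GeoJSON polygons) and serves the derived quantities the statistics
need: neighbour means and the boundary-crossing distance, i.e. the minimum
number of area boundaries crossed when moving from area i to area j (the
graph geodesic on the adjacency graph), used as the variogram lag metric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "AreaGraph",
    "BoundaryDistanceMatrix",
    "build_graph",
    "boundary_distances",
    "neighbor_mean",
    "read_gal",
    "write_gal",
]


class GraphError(ValueError):
    """Invalid adjacency input (unknown area id, self-loop, ...)."""


@dataclass
class AreaGraph:
    """Binary symmetric first-order adjacency over an ordered set of areas.

    Parameters
    ----------
    area_ids
        Ordered opaque labels, one per area.  All matrices produced by this
        package are indexed in this order.
    W
        N x N sparse binary weight matrix, symmetric with zero diagonal.
    """

    area_ids: list
    W: sp.csr_matrix
    _colors: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.area_ids = list(self.area_ids)
        W = sp.csr_matrix(self.W, dtype=float)
        n = len(self.area_ids)
        if n < 2:
            raise GraphError("an areal graph needs at least 2 areas")
        if W.shape != (n, n):
            raise GraphError(f"weight matrix shape {W.shape} != ({n}, {n})")
        if W.diagonal().any():
            raise GraphError("self-loops are not allowed (w_ii must be 0)")
        if (W != W.T).nnz:
            raise GraphError("weight matrix must be symmetric")
        data = W.data
        if data.size and not np.all((data == 0.0) | (data == 1.0)):
            raise GraphError("weights must be binary")
        W.eliminate_zeros()
        self.W = W
        if len(set(map(str, self.area_ids))) != n:
            raise GraphError("area ids must be unique")
        if self.isolated.any():
            iso = [self.area_ids[i] for i in np.flatnonzero(self.isolated)]
            warnings.warn(
                f"{len(iso)} isolated area(s) retained but flagged: {iso}",
                stacklevel=3,
            )

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Number of neighbours of each area (row sums of W)."""
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of areas with no neighbours."""
        return self.degrees == 0

    @property
    def n_components(self) -> int:
        return connected_components(self.W, directed=False)[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the areas adjacent to area ``i``."""
        return self.W.indices[self.W.indptr[i] : self.W.indptr[i + 1]]

    def index(self, area_id) -> int:
        return self.area_ids.index(area_id)

    def coloring(self) -> list:
        """Greedy proper colouring: index arrays with no internal edges.

        Within one colour class no two areas are adjacent, so single-site
        Metropolis updates of a Markov random field can be proposed and
        accepted simultaneously for the whole class.
        """
        if self._colors is None:
            import networkx as nx

            g = nx.from_scipy_sparse_array(self.W)
            cmap = nx.greedy_color(g, strategy="largest_first")
            k = max(cmap.values(), default=0) + 1
            self._colors = [
                np.array(sorted(i for i, c in cmap.items() if c == col), dtype=int)
                for col in range(k)
            ]
        return self._colors

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(cls, edges, area_ids=None) -> "AreaGraph":
        """Build from an iterable of (id_a, id_b) pairs.

        ``area_ids`` may declare extra areas (e.g. islands with no
        neighbours); otherwise ids are taken in order of first appearance.
        """
        edges = list(edges)
        if area_ids is None:
            seen: dict = {}
            for a, b in edges:
                seen.setdefault(a, None)
                seen.setdefault(b, None)
            area_ids = list(seen)
        idx = {a: i for i, a in enumerate(area_ids)}
        rows, cols = [], []
        for a, b in edges:
            if a not in idx or b not in idx:
                missing = a if a not in idx else b
                raise GraphError(f"edge endpoint {missing!r} is not a declared area id")
            if a == b:
                raise GraphError(f"self-loop on area {a!r}")
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
        n = len(area_ids)
        W = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
        )
        W.data[:] = 1.0  # collapse duplicate edges
        return cls(area_ids, W)

    @classmethod
    def from_polygons(cls, geoms, area_ids, contiguity: str = "queen") -> "AreaGraph":
        """Contiguity graph from shapely polygons.

        queen: any shared point makes two areas neighbours; rook: a shared
        boundary segment of positive length is required.
        """
        from shapely.strtree import STRtree

        if contiguity not in ("queen", "rook"):
            raise GraphError(f"unknown contiguity rule {contiguity!r}")
        geoms = list(geoms)
        tree = STRtree(geoms)
        edges = []
        for i, g in enumerate(geoms):
            for j in tree.query(g):
                j = int(j)
                if j <= i:
                    continue
                inter = g.intersection(geoms[j])
                if inter.is_empty:
                    continue
                if contiguity == "queen" or inter.length > 0:
                    edges.append((area_ids[i], area_ids[j]))
        return cls.from_edges(edges, area_ids=area_ids)


@dataclass
class BoundaryDistanceMatrix:
    """Graph geodesic (boundary-crossing) distances between areas.

    ``d[i, j]`` is the minimum number of boundaries crossed moving from area
    i to area j; pairs unreachable within ``max_lag`` carry ``d = -1`` and
    are flagged in ``unreachable``.
    """

    d: np.ndarray
    unreachable: np.ndarray
    max_lag: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=int)
        self.unreachable = np.asarray(self.unreachable, dtype=bool)


def boundary_distances(graph: AreaGraph, max_lag: int | None = None) -> BoundaryDistanceMatrix:
    """All-pairs boundary-crossing distance, truncated beyond ``max_lag``.

    Distances are breadth-first geodesics on the adjacency graph, so
    ``d_ij = 1`` exactly for adjacent pairs.
    """
    n = graph.n
    if max_lag is None:
        max_lag = n  # no effective truncation
    if max_lag < 1:
        raise ValueError("max_lag must be a positive integer")
    dist = shortest_path(graph.W, method="D", directed=False, unweighted=True)
    unreachable = ~np.isfinite(dist) | (dist > max_lag)
    d = np.where(unreachable, -1, np.where(np.isfinite(dist), dist, -1)).astype(int)
    np.fill_diagonal(d, 0)
    np.fill_diagonal(unreachable, False)
    return BoundaryDistanceMatrix(d=d, unreachable=unreachable, max_lag=int(max_lag))


def neighbor_mean(graph: AreaGraph, z) -> np.ndarray:
    """Per-area mean of the first-order neighbours' values.

    Element i is sum_j w_ij z_j / sum_j w_ij.  Isolated areas get NaN (the
    neighbour mean is undefined there) with a warning.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != graph.n:
        raise ValueError(f"z has length {z.shape[-1]}, expected {graph.n}")
    deg = graph.degrees
    if not deg.any():
        raise GraphError("all areas are isolated; neighbour mean undefined everywhere")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (z @ graph.W.T) / deg
    if graph.isolated.any():
        out[..., graph.isolated] = np.nan
        warnings.warn("neighbour mean undefined for isolated areas (set to NaN)", stacklevel=2)
    return out


# -- readers / writer -----------------------------------------------------


def read_gal(path) -> AreaGraph:
    """Read a GAL neighbour-list file.

    Accepts both header dialects: a bare area count, or the four-token
    ``0 n shapefile key`` header used by some GIS exports.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    tokens: list[str] = []
    for ln in lines[1:]:
        tokens.extend(ln.split())
    area_ids: list[str] = []
    nbrs: dict[str, list[str]] = {}
    pos = 0
    for _ in range(n):
        aid, k = tokens[pos], int(tokens[pos + 1])
        pos += 2
        nbrs[aid] = tokens[pos : pos + k]
        pos += k
        area_ids.append(aid)
    edges = [(a, b) for a, lst in nbrs.items() for b in lst]
    return AreaGraph.from_edges(edges, area_ids=area_ids)


def write_gal(graph: AreaGraph, path) -> None:
    """Write the graph as a GAL neighbour-list file (round-trips exactly)."""
    lines = [str(graph.n)]
    for i, aid in enumerate(graph.area_ids):
        nb = graph.neighbors(i)
        lines.append(f"{aid} {len(nb)}")
        lines.append(" ".join(str(graph.area_ids[j]) for j in nb))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_edge_csv(path) -> AreaGraph:
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise GraphError("edge-list CSV needs two columns (from, to)")
    edges = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return AreaGraph.from_edges(edges)


def _read_geojson(path, contiguity: str) -> AreaGraph:
    from shapely.geometry import shape

    obj = json.loads(Path(path).read_text())
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    geoms, ids = [], []
    for k, f in enumerate(feats):
        geoms.append(shape(f["geometry"]))
        props = f.get("properties") or {}
        ids.append(str(props.get("id", props.get("name", k))))
    return AreaGraph.from_polygons(geoms, ids, contiguity=contiguity)


def build_graph(source, contiguity: str = "queen", area_ids=None) -> AreaGraph:
    """Build an :class:`AreaGraph` from a file path or an in-memory edge list.

    File handling is by extension: ``.gal`` neighbour lists, ``.csv`` edge
    lists (two columns, header row), ``.geojson``/``.json`` polygons (queen
    contiguity by default, rook on request).
    """
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix == ".gal":
            return read_gal(source)
        if suffix == ".csv":
            return _read_edge_csv(source)
        if suffix in (".geojson", ".json"):
            return _read_geojson(source, contiguity)
        raise GraphError(f"unrecognised adjacency file type: {source}")
    return AreaGraph.from_edges(source, area_ids=area_ids)
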