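"""Region graphs: the areal units of the analysis and their adjacency.

Adjacency drives the conditional-autoregressive (CAR) priors of the
mortality model and the spatially-correlated pieces of the synthetic-data
generators.  A :class:`RegionGraph` is a connected undirected graph over an
ordered list of region identifiers; connectivity is required so the
intrinsic CAR structure matrix has rank ``n - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["RegionGraph", "make_region_graph", "uganda_region_graph", "UGANDA_REGIONS"]


@dataclass(frozen=True)
class RegionGraph:
    """Ordered regions plus an undirected, connected adjacency structure.

    Edges are stored as sorted index pairs (no self-loops, no duplicates);
    symmetry is by construction since an unordered pair represents both
    directions.
    """

    region_ids: tuple
    edges: tuple
    names: tuple = field(default=None)

    def __post_init__(self):
        n = len(self.region_ids)
        if n < 2:
            raise ValueError("a region graph needs at least 2 regions")
        if len(set(self.region_ids)) != n:
            raise ValueError("region_ids must be unique")
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on region index {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) references an unknown region index")
            canon.add((min(a, b), max(a, b)))
        object.__setattr__(self, "edges", tuple(sorted(canon)))
        if self.names is None:
            object.__setattr__(self, "names", tuple(str(r) for r in self.region_ids))
        g = self.to_networkx()
        if not nx.is_connected(g):
            comps = [sorted(self.region_ids[i] for i in c) for c in nx.connected_components(g)]
            raise ValueError(
                "region graph is disconnected; components: "
                + "; ".join(",".join(map(str, c)) for c in comps)
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(self.edges)
        return g

    def degree(self):
        import numpy as np

        d = np.zeros(self.n_regions, dtype=int)
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def index_of(self, region_id) -> int:
        return self.region_ids.index(region_id)


def make_region_graph(n_regions: int, topology: str = "ring", seed: int = 0,
                      edges=None, grid_shape=None) -> RegionGraph:
    """Build a deterministic region graph with a standard topology.

    Parameters
    ----------
    topology : {"ring", "line", "grid", "custom"}
        ``grid`` uses ``grid_shape`` (rows, cols) or the most nearly square
        factorization of ``n_regions``.  ``custom`` takes ``edges`` as a
        list of index pairs and rejects disconnected inputs, naming the
        components in the error message.
    seed : int
        Accepted for interface uniformity; all standard topologies are
        fully deterministic.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    ids = tuple(f"R{i}" for i in range(n_regions))
    if topology == "line":
        e = [(i, i + 1) for i in range(n_regions - 1)]
    elif topology == "ring":
        if n_regions == 2:
            e = [(0, 1)]
        else:
            e = [(i, (i + 1) % n_regions) for i in range(n_regions)]
    elif topology == "grid":
        if grid_shape is None:
            r = int(n_regions**0.5)
            while n_regions % r:
                r -= 1
            grid_shape = (r, n_regions // r)
        rows, cols = grid_shape
        if rows * cols != n_regions:
            raise ValueError(f"grid_shape {grid_shape} does not tile {n_regions} regions")
        e = []
        for i in range(rows):
            for j in range(cols):
                k = i * cols + j
                if j + 1 < cols:
                    e.append((k, k + 1))
                if i + 1 < rows:
                    e.append((k, k + cols))
    elif topology == "custom":
        if edges is None:
            raise ValueError("custom topology requires an edge list")
        e = list(edges)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return RegionGraph(region_ids=ids, edges=tuple(e))


#: The 10 analysis regions of the 2011 Uganda DHS.
UGANDA_REGIONS = (
    "Central 1", "Central 2", "Kampala", "East Central", "Eastern",
    "North", "Karamoja", "West Nile", "Western", "Southwest",
)

# Approximate adjacency digitized by eye from the 2011 DHS region map.
# SYNTHETIC STAND-IN: the authoritative adjacency is not published with the
# analysis dataset; override with a custom edge list for real work.
_UGANDA_EDGES = (
    ("Kampala", "Central 1"), ("Kampala", "Central 2"),
    ("Central 1", "Central 2"), ("Central 1", "Southwest"), ("Central 1", "Western"),
    ("Central 2", "East Central"), ("Central 2", "Western"), ("Central 2", "North"),
    ("East Central", "Eastern"),
    ("Eastern", "Karamoja"), ("Eastern", "North"),
    ("Karamoja", "North"),
    ("North", "West Nile"), ("North", "Western"),
    ("Western", "West Nile"), ("Western", "Southwest"),
)


def uganda_region_graph() -> RegionGraph:
    """Default 10-region graph with the approximate DHS-2011 adjacency.

    The edge list is a documented approximation (see module notes); all CAR
    code accepts any :class:`RegionGraph`, so analyses that depend on the
    true geography should supply their own adjacency.
    """
    idx = {r: i for i, r in enumerate(UGANDA_REGIONS)}
    edges = tuple((idx[a], idx[b]) for a, b in _UGANDA_EDGES)
    return RegionGraph(region_ids=UGANDA_REGIONS, edges=edges)
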