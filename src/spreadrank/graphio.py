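"""Network data model, edge-list / Pajek I/O, and topology statistics.

The package works on undirected simple graphs.  Internally nodes are dense
0-based integer indices; original string labels (from edge-list or Pajek
files) are retained for reporting.  Edges are stored as a canonical
``(E, 2)`` integer array with the smaller endpoint first and rows sorted
lexicographically, which makes equality, hashing into sparse adjacency, and
round-trip file identity straightforward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "TopologyStats",
    "read_edge_list",
    "write_edge_list",
    "read_pajek",
    "giant_component",
    "topology_stats",
]


class GraphParseError(ValueError):
    """Raised when an input graph file is malformed."""


def _canonical_edges(edges: Iterable[tuple[int, int]] | np.ndarray) -> np.ndarray:
    """Canonicalize to a sorted, deduplicated (E,2) int64 array, min index first.

    Self-loops are rejected here; callers that need to *drop* (rather than
    reject) loops and duplicates filter before canonicalizing.
    """
    arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges, dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2)
    if np.any(arr[:, 0] == arr[:, 1]):
        raise ValueError("self-loops are not allowed in a Network")
    arr = np.sort(arr, axis=1)
    arr = np.unique(arr, axis=0)
    return arr


@dataclass(frozen=True)
class Network:
    """Undirected simple graph with dense 0-based node indices.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; indices run 0 .. n_nodes-1.
    edges : ndarray of shape (E, 2)
        Canonical edge array (smaller index first, rows sorted, no
        duplicates, no self-loops).  Any iterable of pairs is accepted and
        canonicalized.
    node_labels : tuple of str, optional
        Original labels, one per node, for reporting.
    """

    n_nodes: int
    edges: np.ndarray
    node_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        edges = _canonical_edges(self.edges)
        object.__setattr__(self, "edges", edges)
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be nonnegative")
        if edges.size and edges.max() >= self.n_nodes:
            raise ValueError("edge endpoint out of range")
        if edges.size and edges.min() < 0:
            raise ValueError("negative node index")
        if self.node_labels is not None and len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal n_nodes")

    # -- derived views -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        """Degree of every node as an int64 array of length n_nodes."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes).astype(np.int64)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix in CSR form."""
        if self.n_edges == 0:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.n_edges)
        a = sp.csr_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a

    def neighbor_lists(self) -> list[np.ndarray]:
        """Adjacency as a list of neighbor index arrays."""
        a = self.adjacency()
        return [a.indices[a.indptr[v]: a.indptr[v + 1]] for v in range(self.n_nodes)]

    def to_igraph(self):
        import igraph as ig

        return ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.n_nodes == other.n_nodes and np.array_equal(self.edges, other.edges)


@dataclass(frozen=True)
class TopologyStats:
    """Summary topology statistics of a network.

    ``mean_distance`` averages shortest-path hop counts over unordered
    distinct node pairs of the giant component.  ``assortativity`` is the
    Pearson correlation of the degrees at the two ends of an edge (each edge
    counted in both orientations); ``None`` when undefined (zero degree
    variance at either end, or no edges).
    """

    N: int
    E: int
    mean_degree: float
    mean_distance: Optional[float]
    assortativity: Optional[float]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_edge_list(source: IO[str]) -> Network:
    """Read a whitespace-separated edge list into a Network.

    Each non-empty, non-``#`` line must hold exactly two labels.  Labels are
    mapped to dense indices in first-seen order, except when the labels are
    exactly the integers 0..N-1, in which case their numeric values are used
    directly (so that :func:`write_edge_list` output reads back to an
    identical network).  Duplicate edges and self-loops are dropped (counts
    logged).
    """
    label_order: dict[str, int] = {}
    label_pairs: list[tuple[str, str]] = []
    n_loop = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphParseError(f"line {lineno}: expected two labels, got {len(parts)}")
        for lab in parts:
            if lab not in label_order:
                label_order[lab] = len(label_order)
        if parts[0] == parts[1]:
            n_loop += 1
            continue
        label_pairs.append((parts[0], parts[1]))

    labels = list(label_order)
    if labels and all(lab.isdigit() for lab in labels):
        numeric = sorted(int(lab) for lab in labels)
        if numeric == list(range(len(labels))):
            label_order = {str(i): i for i in range(len(labels))}
            labels = [str(i) for i in range(len(labels))]

    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_dup = 0
    for a, b in label_pairs:
        u, v = label_order[a], label_order[b]
        key = (min(u, v), max(u, v))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(key)
    if n_dup or n_loop:
        logger.info("read_edge_list: dropped %d duplicate edge(s), %d self-loop(s)", n_dup, n_loop)
    return Network(
        n_nodes=len(labels),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        node_labels=tuple(labels) if labels else None,
    )


def write_edge_list(net: Network, sink: IO[str]) -> None:
    """Write one edge per line, smaller index first, lexicographically sorted.

    Labels are written when present, indices otherwise.  Output round-trips
    through :func:`read_edge_list` for any network without isolated nodes.
    """
    labels = net.node_labels
    for u, v in net.edges:
        if labels is not None:
            sink.write(f"{labels[u]} {labels[v]}\n")
        else:
            sink.write(f"{u} {v}\n")


def read_pajek(source: IO[str]) -> Network:
    """Read a Pajek ``.net`` file (``*Vertices`` + ``*Edges``/``*Arcs``).

    Vertex numbering is 1-based in the file and converted to 0-based.  Arcs
    are treated as undirected edges; trailing edge weights are ignored.
    """
    lines = source.read().splitlines()
    n_vertices: Optional[int] = None
    labels: dict[int, str] = {}
    edges: list[tuple[int, int]] = []
    section = None
    saw_edge_section = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            parts = line.split()
            if len(parts) < 2 or not parts[1].isdigit():
                raise GraphParseError(f"line {lineno}: malformed *Vertices header")
            n_vertices = int(parts[1])
            section = "vertices"
            continue
        if low.startswith("*edges") or low.startswith("*arcs"):
            section = "edges"
            saw_edge_section = True
            continue
        if line.startswith("*"):
            section = "other"
            continue
        if section == "vertices":
            parts = line.split(None, 1)
            vid = int(parts[0])
            if len(parts) > 1:
                lab = parts[1].strip()
                if lab.startswith('"'):
                    lab = lab[1:].split('"', 1)[0]
                else:
                    lab = lab.split()[0]
                labels[vid] = lab
        elif section == "edges":
            parts = line.split()
            if len(parts) < 2:
                raise GraphParseError(f"line {lineno}: malformed edge line")
            u, v = int(parts[0]), int(parts[1])
            if u != v:
                edges.append((min(u, v) - 1, max(u, v) - 1))
    if n_vertices is None:
        raise GraphParseError("missing *Vertices section")
    if not saw_edge_section:
        raise GraphParseError("missing *Edges/*Arcs section")
    if labels and len(labels) != n_vertices:
        raise GraphParseError(
            f"*Vertices declares {n_vertices} vertices but {len(labels)} are listed"
        )
    if labels and (min(labels) < 1 or max(labels) > n_vertices):
        raise GraphParseError("vertex id out of declared range")
    if edges and (max(max(e) for e in edges) >= n_vertices or min(min(e) for e in edges) < 0):
        raise GraphParseError("edge endpoint outside declared vertex range")
    label_tuple = tuple(labels.get(i + 1, str(i + 1)) for i in range(n_vertices)) if labels else None
    return Network(n_nodes=n_vertices, edges=np.array(edges, dtype=np.int64).reshape(-1, 2), node_labels=label_tuple)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def giant_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component, reindexed densely.

    Ties between equally large components are broken in favour of the one
    containing the smallest original node index.  Relative node order is
    preserved in the reindexing.
    """
    if net.n_nodes == 0:
        raise ValueError("giant_component of an empty network is undefined")
    n_comp, comp = connected_components(net.adjacency(), directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    # argmax returns the first maximal component label; labels are assigned
    # in order of the smallest member index, so ties resolve as documented
    best = int(np.argmax(sizes))
    keep = np.flatnonzero(comp == best)
    remap = -np.ones(net.n_nodes, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    if net.n_edges:
        mask = (comp[net.edges[:, 0]] == best)
        sub_edges = remap[net.edges[mask]]
    else:
        sub_edges = np.empty((0, 2), dtype=np.int64)
    labels = tuple(net.node_labels[i] for i in keep) if net.node_labels is not None else None
    return Network(n_nodes=keep.size, edges=sub_edges, node_labels=labels)


def mean_shortest_path_length(
    net: Network,
    exact: bool = True,
    n_sources: int = 1000,
    seed: int | None = 0,
) -> float:
    """Average hop distance over unordered distinct pairs of a connected graph.

    With ``exact=False`` a uniform sample of BFS source nodes estimates the
    same quantity (the per-source mean distance to all other nodes is an
    unbiased estimator of the pair average, by symmetry of the distance
    matrix).  Pass the giant component for possibly disconnected graphs.
    """
    n = net.n_nodes
    if n < 2 or net.n_edges == 0:
        raise ValueError("mean distance needs >= 2 nodes and >= 1 edge")
    a = net.adjacency()
    if exact or n_sources >= n:
        sources = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sources = rng.choice(n, size=n_sources, replace=False)
    d = dijkstra(a, directed=False, unweighted=True, indices=sources)
    if np.isinf(d).any():
        raise ValueError("graph is disconnected; take the giant component first")
    # each row includes the zero self-distance: divide by n-1 per source
    return float(d.sum() / (sources.size * (n - 1)))


def degree_assortativity(net: Network) -> Optional[float]:
    """Pearson correlation of end-point degrees over both edge orientations.

    Returns ``None`` when either end-degree sequence has zero variance
    (e.g. regular graphs) or the network has no edges.  Using full degrees
    rather than excess degrees leaves the value unchanged because Pearson
    correlation is shift-invariant.
    """
    if net.n_edges == 0:
        return None
    deg = net.degrees()
    x = np.concatenate([deg[net.edges[:, 0]], deg[net.edges[:, 1]]]).astype(float)
    y = np.concatenate([deg[net.edges[:, 1]], deg[net.edges[:, 0]]]).astype(float)
    if np.var(x) == 0 or np.var(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def topology_stats(
    net: Network,
    exact_distances: bool = True,
    n_sources: int = 1000,
    seed: int | None = 0,
) -> TopologyStats:
    """Node/edge counts, mean degree, mean distance and degree assortativity.

    Mean distance is computed on the giant component (disconnected pairs
    excluded by construction).  ``exact_distances=False`` switches to
    sampled-source BFS with ``n_sources`` seeded sources.
    """
    n, e = net.n_nodes, net.n_edges
    mean_deg = 2.0 * e / n if n else 0.0
    if e == 0:
        return TopologyStats(N=n, E=0, mean_degree=mean_deg, mean_distance=None, assortativity=None)
    gc = giant_component(net)
    mean_dist = mean_shortest_path_length(gc, exact=exact_distances, n_sources=n_sources, seed=seed)
    return TopologyStats(
        N=n,
        E=e,
        mean_degree=mean_deg,
        mean_distance=mean_dist,
        assortativity=degree_assortativity(net),
    )
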