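"""Node-importance metrics: degree k, H-index h, coreness s, betweenness b.

These four metrics are the class variables of the mean-field SIS models.
For every node the chain ``coreness <= h_index <= degree`` holds, and
iterating the neighbour H-index operator starting from the degree sequence
converges to the coreness (degree is the initial state, the H-index the
first iterate, coreness the fixed point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphio import Network

__all__ = [
    "MetricVector",
    "METRIC_NAMES",
    "degree",
    "h_index",
    "h_operator",
    "coreness",
    "betweenness",
    "compute_metric",
    "all_metrics",
    "metric_maxima",
]

METRIC_NAMES = ("degree", "h_index", "coreness", "betweenness")


@dataclass(frozen=True)
class MetricVector:
    """A named nonnegative score per node (integer for k, h, s)."""

    metric_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ValueError("metric values must be a 1-d array")
        if vals.size and vals.min() < 0:
            raise ValueError("metric values must be nonnegative")

    def max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0


def degree(net: Network) -> MetricVector:
    """Number of neighbours of each node."""
    return MetricVector("degree", net.degrees())


def _h_of_multiset(sorted_desc: np.ndarray) -> int:
    """H-index of a descending-sorted value array: max h with >= h entries >= h."""
    if sorted_desc.size == 0:
        return 0
    ranks = np.arange(1, sorted_desc.size + 1)
    ok = sorted_desc >= ranks
    return int(ranks[ok][-1]) if ok.any() else 0


def h_operator(net: Network, values: np.ndarray | MetricVector) -> MetricVector:
    """Apply the neighbour H-index operator to a per-node value vector.

    ``out[i]`` is the largest h such that at least h neighbours of i carry a
    value >= h.  Applied to the degree sequence this yields the H-index;
    iterated to its fixed point it yields the coreness.
    """
    vals = values.values if isinstance(values, MetricVector) else np.asarray(values)
    if vals.shape != (net.n_nodes,):
        raise ValueError("values length must equal n_nodes")
    nbrs = net.neighbor_lists()
    out = np.zeros(net.n_nodes, dtype=np.int64)
    for i, nb in enumerate(nbrs):
        out[i] = _h_of_multiset(np.sort(vals[nb])[::-1])
    return MetricVector("h_operator", out)


def h_index(net: Network) -> MetricVector:
    """Largest h such that the node has at least h neighbours of degree >= h."""
    mv = h_operator(net, net.degrees())
    return MetricVector("h_index", mv.values)


def coreness(net: Network) -> MetricVector:
    """k-shell index via iterative minimum-degree peeling."""
    g = net.to_igraph()
    return MetricVector("coreness", np.asarray(g.coreness(), dtype=np.int64))


def betweenness(net: Network, count_paths: bool = False) -> MetricVector:
    """Shortest-path throughput of each node, endpoints excluded, unnormalized.

    Default is the standard pair-dependency sum over unordered pairs,
    sigma_st(i)/sigma_st, which splits credit fractionally when geodesics
    tie and coincides with the literal path count when they are unique.
    Pairs in different components contribute zero.

    ``count_paths=True`` instead returns the literal number of geodesics
    through each node, sum over pairs of sigma_st(i) = sigma_si * sigma_it.
    This variant enumerates the full distance and path-count matrices and is
    intended for small graphs (sensitivity analysis of the tie convention).
    """
    if count_paths:
        return MetricVector("betweenness", _geodesic_count(net))
    g = net.to_igraph()
    vals = np.asarray(g.betweenness(directed=False), dtype=float)
    return MetricVector("betweenness", vals)


def _geodesic_count(net: Network) -> np.ndarray:
    """Literal count of shortest paths through each node (O(N^3) memory/time)."""
    n = net.n_nodes
    nbrs = net.neighbor_lists()
    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=float)
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for v in nbrs[u]:
                    if dist[s, v] == -1:
                        dist[s, v] = d + 1
                        nxt.append(int(v))
                    if dist[s, v] == d + 1:
                        sigma[s, v] += sigma[s, u]
            frontier = nxt
            d += 1
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s, t] < 0:
                continue
            through = (dist[s] >= 0) & (dist[t] >= 0) & (dist[s] + dist[t] == dist[s, t])
            through[s] = through[t] = False
            out[through] += sigma[s][through] * sigma[t][through]
    return out


def compute_metric(net: Network, name: str) -> MetricVector:
    """Dispatch a metric by name (one of ``METRIC_NAMES``)."""
    funcs = {"degree": degree, "h_index": h_index, "coreness": coreness, "betweenness": betweenness}
    if name not in funcs:
        raise ValueError(f"unknown metric {name!r}; expected one of {METRIC_NAMES}")
    return funcs[name](net)


def all_metrics(net: Network) -> dict[str, MetricVector]:
    """All four metrics keyed by name."""
    return {name: compute_metric(net, name) for name in METRIC_NAMES}


def metric_maxima(net: Network) -> dict[str, float]:
    """Per-metric maximum value, for reporting network summaries."""
    return {name: mv.max() for name, mv in all_metrics(net).items()}
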