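"""Synthetic network generators.

Two families are provided:

* :func:`barabasi_albert` — growing preferential-attachment networks used as
  the scale-free study substrates (the two reference configurations are
  ``N=5000, m=30`` with mean degree ~60 and ``N=10000, m=100`` with mean
  degree ~200).
* :func:`fixture_graph` — small deterministic graphs (star, path, cycle,
  complete, circulant-regular) whose centralities and mean-field quantities
  have closed forms, used as oracles in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphio import Network

__all__ = ["BAParams", "barabasi_albert", "fixture_graph"]


@dataclass(frozen=True)
class BAParams:
    """Parameters of the preferential-attachment construction.

    ``m0`` nodes start as a complete seed clique; each of the remaining
    ``n_nodes - m0`` nodes attaches to ``m`` distinct existing nodes chosen
    with probability proportional to current degree.  Requires
    ``1 <= m <= m0 < n_nodes``.  By default ``m0 = m``.
    """

    n_nodes: int
    m: int
    m0: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        m0 = self.m if self.m0 is None else self.m0
        object.__setattr__(self, "m0", m0)
        if not (1 <= self.m <= m0 < self.n_nodes):
            raise ValueError(f"require 1 <= m <= m0 < n_nodes, got m={self.m}, m0={m0}, N={self.n_nodes}")

    @property
    def expected_edges(self) -> int:
        """Exact edge count: seed clique plus m per added node."""
        return self.m0 * (self.m0 - 1) // 2 + (self.n_nodes - self.m0) * self.m


def barabasi_albert(params: BAParams) -> Network:
    """Grow a simple connected preferential-attachment network.

    Degree-proportional sampling without replacement is realized by drawing
    uniformly from a list holding each node once per unit of degree and
    rejecting repeats, so no multi-edges are ever created and the edge count
    equals ``m0(m0-1)/2 + (N-m0) m`` exactly.  Bit-reproducible for a fixed
    seed.
    """
    n, m, m0 = params.n_nodes, params.m, params.m0
    rng = np.random.default_rng(params.seed)

    edges: list[tuple[int, int]] = [(i, j) for i in range(m0) for j in range(i + 1, m0)]
    # degree-weighted urn: node v appears deg(v) times
    repeated = np.empty(2 * params.expected_edges, dtype=np.int64)
    pos = 0
    for i, j in edges:
        repeated[pos] = i
        repeated[pos + 1] = j
        pos += 2

    for new in range(m0, n):
        chosen: list[int] = []
        chosen_set: set[int] = set()
        while len(chosen) < m:
            # draw in small batches; duplicates are rejected
            draw = repeated[rng.integers(0, pos, size=2 * (m - len(chosen)))]
            for t in draw:
                t = int(t)
                if t not in chosen_set:
                    chosen_set.add(t)
                    chosen.append(t)
                    if len(chosen) == m:
                        break
        for t in chosen:
            edges.append((t, new))
            repeated[pos] = t
            repeated[pos + 1] = new
            pos += 2

    return Network(n_nodes=n, edges=np.array(edges, dtype=np.int64))


def fixture_graph(kind: str, **size_params: int) -> Network:
    """Deterministic toy graphs with known closed-form properties.

    Kinds and their size parameters:

    * ``complete``: ``n`` — clique K_n (n >= 1)
    * ``star``: ``leaves`` — one hub plus ``leaves`` degree-1 nodes
    * ``path``: ``n`` — path graph P_n (n >= 1)
    * ``cycle``: ``n`` — cycle C_n (n >= 3)
    * ``regular``: ``n``, ``k`` — circulant k-regular graph; offsets
      1..k//2 on each side, plus the antipodal offset n/2 when k is odd
      (requires n even in that case, i.e. n*k even overall)
    """
    if kind == "complete":
        n = size_params["n"]
        if n < 1:
            raise ValueError("complete graph needs n >= 1")
        return Network(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
    if kind == "star":
        leaves = size_params["leaves"]
        if leaves < 1:
            raise ValueError("star needs >= 1 leaf")
        return Network(leaves + 1, [(0, i) for i in range(1, leaves + 1)])
    if kind == "path":
        n = size_params["n"]
        if n < 1:
            raise ValueError("path needs n >= 1")
        return Network(n, [(i, i + 1) for i in range(n - 1)])
    if kind == "cycle":
        n = size_params["n"]
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        return Network(n, [(i, (i + 1) % n) for i in range(n)])
    if kind == "regular":
        n, k = size_params["n"], size_params["k"]
        if k < 0 or k >= n or (n * k) % 2 != 0:
            raise ValueError("regular graph needs 0 <= k < n with n*k even")
        if k % 2 == 1 and n % 2 != 0:
            raise ValueError("odd k requires even n (circulant construction)")
        edges = []
        for off in range(1, k // 2 + 1):
            edges.extend((i, (i + off) % n) for i in range(n))
        if k % 2 == 1:
            edges.extend((i, i + n // 2) for i in range(n // 2))
        return Network(n, edges)
    raise ValueError(f"unknown fixture kind {kind!r}")
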