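"""Uniform and centrality-targeted immunization experiments.

Targeted immunization removes the top ``g N`` nodes ranked by a metric
(degree, H-index, coreness, or betweenness) from the contact graph before
the epidemic is simulated; this realizes the metric-cutoff selection
g = sum_{x > x_t} P(x) on empirical data, with boundary ties broken by node
index so that exactly ``round(g N)`` nodes are always immunized.  Uniform
immunization removes a random ``g N``-node sample.  At the mean-field
level, uniform immunization is equivalently the substitution
lambda -> lambda (1 - g), which is provided separately.

Prevalence under immunization is always counted against the original node
count, so the reported ratio rho_g / rho_0 is comparable across g; the
immunization threshold g_c is the smallest g on the grid driving that
ratio (numerically) to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .centrality import MetricVector, compute_metric, METRIC_NAMES
from .graphio import Network
from .meanfield import EpidemicParams, MetricClasses, stationary_prevalence
from .montecarlo import DEFAULT_BURN_IN, DEFAULT_DT, DEFAULT_T_MAX, ensemble_prevalence

__all__ = [
    "STRATEGIES",
    "ImmunizationCurve",
    "select_targeted",
    "select_uniform",
    "apply_immunization",
    "mf_uniform_immunized_prevalence",
    "immunization_curve",
    "immunization_threshold",
]

STRATEGIES = ("uniform",) + METRIC_NAMES


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ImmunizationCurve:
    """Prevalence-versus-immunized-fraction curve for one strategy."""

    strategy: str
    g_grid: np.ndarray
    rho_g: np.ndarray
    stderr: np.ndarray
    rho_0: float

    @property
    def ratio(self) -> np.ndarray:
        return self.rho_g / self.rho_0


def select_targeted(net: Network, metric: MetricVector, g: float) -> tuple[np.ndarray, Optional[float]]:
    """The ``round(g N)`` nodes with the largest metric values, plus cutoff.

    Boundary ties are broken by ascending node index.  The cutoff is the
    smallest selected metric value — the empirical upper threshold x_t such
    that all nodes with metric above it are immunized.
    """
    if not (0 <= g <= 1):
        raise ValueError("g must lie in [0, 1]")
    n = net.n_nodes
    r = _round_half_up(g * n)
    if r == 0:
        return np.empty(0, dtype=np.int64), None
    order = np.lexsort((np.arange(n), -np.asarray(metric.values, dtype=float)))
    chosen = np.sort(order[:r])
    cutoff = float(np.asarray(metric.values)[order[r - 1]])
    return chosen, cutoff


def select_uniform(net: Network, g: float, seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """A uniform random sample of ``round(g N)`` nodes, seeded."""
    if not (0 <= g <= 1):
        raise ValueError("g must lie in [0, 1]")
    r = _round_half_up(g * net.n_nodes)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(net.n_nodes, size=r, replace=False))


def apply_immunization(net: Network, nodes: Sequence[int] | np.ndarray) -> Network:
    """Remove all edges incident to the immunized nodes.

    The node set itself is preserved (immunized nodes become isolated) so
    that indices keep their identity and prevalence can be counted against
    the original N.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    if nodes.size and (nodes.min() < 0 or nodes.max() >= net.n_nodes):
        raise ValueError("immunized node index out of range")
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[nodes] = True
    if net.n_edges:
        keep = ~(mask[net.edges[:, 0]] | mask[net.edges[:, 1]])
        edges = net.edges[keep]
    else:
        edges = net.edges
    return Network(n_nodes=net.n_nodes, edges=edges, node_labels=net.node_labels)


def mf_uniform_immunized_prevalence(
    classes: MetricClasses, params: EpidemicParams, g: float
) -> float:
    """Mean-field prevalence under uniform immunization of a fraction g.

    Uniform immunization reduces the effective spreading rate by (1 - g);
    the prevalence is the stationary solution at lambda (1 - g), reaching
    zero at g >= 1 - lambda_c / lambda.
    """
    if not (0 <= g <= 1):
        raise ValueError("g must lie in [0, 1]")
    return stationary_prevalence(classes, params.lam * (1.0 - g)).rho


def immunization_curve(
    net: Network,
    strategy: str,
    params: EpidemicParams | None = None,
    g_grid: Sequence[float] | None = None,
    runs: int = 100,
    seed: int = 0,
    t_max: float = DEFAULT_T_MAX,
    burn_in: float = DEFAULT_BURN_IN,
    dt: float = DEFAULT_DT,
    metric: MetricVector | None = None,
) -> ImmunizationCurve:
    """Monte Carlo prevalence ratio rho_g/rho_0 along a grid of g values.

    The ranking metric is computed once on the intact network (static
    targeting: no re-ranking after removal).  For each g the selected nodes
    are pruned from the contact graph, the SIS ensemble is run with
    prevalence counted over the original N, and the ratio is taken against
    the g = 0 entry, so the curve starts at exactly 1.  Raises if the
    unimmunized prevalence is zero (lambda below the network's effective
    threshold — increase lambda).

    A precomputed ``metric`` may be passed to avoid recomputing expensive
    rankings (it must match the strategy).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if params is None:
        params = EpidemicParams(lam=0.15)
    grid = np.asarray(g_grid if g_grid is not None else np.arange(0.0, 0.5001, 0.02), dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ValueError("g grid must start at 0")

    if strategy != "uniform":
        if metric is None:
            metric = compute_metric(net, strategy)
        elif metric.metric_name != strategy:
            raise ValueError("supplied metric does not match strategy")

    ss = np.random.SeedSequence(seed)
    select_ss, mc_ss = ss.spawn(2)
    mc_children = mc_ss.spawn(grid.size)
    uniform_children = select_ss.spawn(grid.size)

    rho = np.zeros(grid.size)
    err = np.zeros(grid.size)
    for i, g in enumerate(grid):
        if strategy == "uniform":
            nodes = select_uniform(net, float(g), seed=uniform_children[i])
        else:
            nodes, _ = select_targeted(net, metric, float(g))
        pruned = apply_immunization(net, nodes)
        blocked = np.zeros(net.n_nodes, dtype=bool)
        blocked[nodes] = True
        res = ensemble_prevalence(
            pruned, params, runs=runs, t_max=t_max, burn_in=burn_in, dt=dt,
            seed=mc_children[i], blocked=blocked, denominator=net.n_nodes,
        )
        rho[i], err[i] = res.mean, res.stderr
    if rho[0] <= 0:
        raise ValueError(
            "prevalence without immunization is zero; lambda is below the "
            "network's effective epidemic threshold — use a larger lambda"
        )
    return ImmunizationCurve(strategy=strategy, g_grid=grid, rho_g=rho, stderr=err, rho_0=float(rho[0]))


def immunization_threshold(curve: ImmunizationCurve, epsilon: float = 0.005) -> float:
    """Smallest grid g with rho_g/rho_0 <= epsilon; +inf if never reached."""
    below = np.flatnonzero(curve.ratio <= epsilon)
    return float(curve.g_grid[below[0]]) if below.size else math.inf
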