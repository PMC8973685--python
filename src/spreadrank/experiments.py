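"""End-to-end experiment drivers.

Four experiment families are orchestrated here, each mapping to one figure
family of the study design:

* :func:`spreading_comparison` — stationary prevalence versus spreading
  rate for the four mean-field models and the Monte Carlo baseline.
* :func:`threshold_scan` — theoretical epidemic thresholds <x>/<x^2>
  against the onset of nonzero stationary prevalence on a rate grid.
* :func:`immunization_comparison` — prevalence-ratio curves and
  immunization thresholds for uniform plus four targeted strategies.
* :func:`degree_distribution_report` — empirical degree distribution and a
  descriptive log-log straightness score.

:func:`run` executes a YAML-configurable pipeline writing CSV tables with a
provenance header (config hash, master seed, package version); identical
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .centrality import METRIC_NAMES, all_metrics, compute_metric, metric_maxima
from .generators import BAParams, barabasi_albert
from .graphio import Network, read_edge_list, topology_stats
from .meanfield import (
    EpidemicParams,
    build_classes,
    epidemic_threshold,
    prevalence_curve,
    stationary_prevalence,
)
from .montecarlo import DEFAULT_BURN_IN, DEFAULT_DT, DEFAULT_T_MAX, ensemble_prevalence
from .immunization import STRATEGIES, immunization_curve, immunization_threshold

__all__ = [
    "ExperimentConfig",
    "SpreadingComparison",
    "ImmunizationComparison",
    "spreading_comparison",
    "threshold_scan",
    "immunization_comparison",
    "degree_distribution_report",
    "run",
]


@dataclass(frozen=True)
class SpreadingComparison:
    """Prevalence-vs-lambda table and the mean-field model closest to MC."""

    table: pd.DataFrame
    closest_model: str


@dataclass(frozen=True)
class ImmunizationComparison:
    """Ratio curves per strategy, immunization thresholds, and ranking."""

    table: pd.DataFrame
    thresholds: dict[str, float]
    ranking: list[str]


def spreading_comparison(
    net: Network,
    lambda_grid: Sequence[float],
    rho0: float = 0.05,
    runs: int = 20,
    seed: int = 0,
    t_max: float = DEFAULT_T_MAX,
    burn_in: float = DEFAULT_BURN_IN,
    dt: float = DEFAULT_DT,
    metrics: Sequence[str] = METRIC_NAMES,
) -> SpreadingComparison:
    """Stationary prevalence per lambda: four HMF models plus MC ensemble.

    Also reports which mean-field model's curve is closest to the Monte
    Carlo curve in mean squared difference.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    table = pd.DataFrame({"lambda": grid})
    classes = {m: build_classes(compute_metric(net, m)) for m in metrics}
    for m in metrics:
        table[f"hmf_{m}"] = prevalence_curve(classes[m], grid)["rho"].to_numpy()
    ss = np.random.SeedSequence(seed)
    mc_mean = np.zeros(grid.size)
    mc_err = np.zeros(grid.size)
    for i, (lam, child) in enumerate(zip(grid, ss.spawn(grid.size))):
        res = ensemble_prevalence(
            net, EpidemicParams(lam=float(lam), rho0=rho0), runs=runs,
            t_max=t_max, burn_in=burn_in, dt=dt, seed=child,
        )
        mc_mean[i], mc_err[i] = res.mean, res.stderr
    table["mc"] = mc_mean
    table["mc_stderr"] = mc_err
    mse = {m: float(np.mean((table[f"hmf_{m}"] - mc_mean) ** 2)) for m in metrics}
    return SpreadingComparison(table=table, closest_model=min(mse, key=mse.get))


def threshold_scan(
    net: Network,
    metrics: Sequence[str] = METRIC_NAMES,
    n_grid: int = 40,
    onset_tol: float = 1e-6,
) -> pd.DataFrame:
    """Theoretical threshold <x>/<x^2> vs the onset of endemic prevalence.

    For each metric a lambda grid spanning [0, 2 lambda_c] is scanned with
    the stationary solver; the onset is the first grid point with rho >
    ``onset_tol``.  Columns: metric, lambda_c_theory, lambda_c_onset,
    grid_step.
    """
    rows = []
    for m in metrics:
        classes = build_classes(compute_metric(net, m))
        lam_c = epidemic_threshold(classes)
        grid = np.linspace(0.0, 2.0 * lam_c, n_grid + 1)
        onset = math.inf
        for lam in grid:
            if stationary_prevalence(classes, float(lam)).rho > onset_tol:
                onset = float(lam)
                break
        rows.append((m, lam_c, onset, float(grid[1] - grid[0])))
    return pd.DataFrame(rows, columns=["metric", "lambda_c_theory", "lambda_c_onset", "grid_step"])


def immunization_comparison(
    net: Network,
    lam: float = 0.15,
    rho0: float = 0.05,
    g_grid: Sequence[float] | None = None,
    runs: int = 100,
    seed: int = 0,
    t_max: float = DEFAULT_T_MAX,
    burn_in: float = DEFAULT_BURN_IN,
    dt: float = DEFAULT_DT,
    strategies: Sequence[str] = STRATEGIES,
    epsilon: float = 0.005,
) -> ImmunizationComparison:
    """Ratio curves rho_g/rho_0 for uniform + targeted strategies.

    Returns the per-strategy curves (columns ``ratio_<strategy>`` and
    ``stderr_<strategy>``), the immunization thresholds g_c (smallest grid
    g with ratio <= epsilon, +inf when not reached), and the strategies
    ranked by ascending g_c (ties broken by the area under the ratio
    curve, then by name for determinism).
    """
    params = EpidemicParams(lam=lam, rho0=rho0)
    grid = np.asarray(g_grid if g_grid is not None else np.arange(0.0, 0.5001, 0.02), dtype=float)
    ss = np.random.SeedSequence(seed)
    children = dict(zip(strategies, ss.spawn(len(strategies))))
    table = pd.DataFrame({"g": grid})
    thresholds: dict[str, float] = {}
    areas: dict[str, float] = {}
    for strat in strategies:
        curve = immunization_curve(
            net, strat, params=params, g_grid=grid, runs=runs,
            seed=int(children[strat].generate_state(1, dtype=np.uint32)[0]),
            t_max=t_max, burn_in=burn_in, dt=dt,
        )
        table[f"ratio_{strat}"] = curve.ratio
        table[f"stderr_{strat}"] = curve.stderr / curve.rho_0
        thresholds[strat] = immunization_threshold(curve, epsilon=epsilon)
        areas[strat] = float(np.trapezoid(curve.ratio, grid))
    ranking = sorted(strategies, key=lambda s: (thresholds[s], areas[s], s))
    return ImmunizationComparison(table=table, thresholds=thresholds, ranking=ranking)


def degree_distribution_report(
    net: Network, k_min: Optional[int] = None
) -> tuple[pd.DataFrame, Optional[float]]:
    """Empirical degree distribution P(k) and a log-log straightness score.

    The score is the coefficient of determination R^2 of a least-squares
    line fit to (log10 k, log10 P(k)) over degrees k >= k_min (default: the
    smallest positive degree).  It is descriptive only — a value near 1
    indicates an approximately power-law tail.  ``None`` when fewer than 3
    distinct positive degrees support the fit.
    """
    if net.n_edges == 0:
        raise ValueError("degree distribution of an edgeless network is degenerate")
    deg = net.degrees()
    ks, counts = np.unique(deg, return_counts=True)
    pk = counts / net.n_nodes
    table = pd.DataFrame({"k": ks, "p": pk})
    if k_min is None:
        pos = ks[ks > 0]
        k_min = int(pos.min()) if pos.size else 1
    sel = ks >= k_min
    if sel.sum() < 3:
        return table, None
    x = np.log10(ks[sel].astype(float))
    y = np.log10(pk[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else None
    return table, r2


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Pipeline configuration; mirrors the CLI flags.

    The network source is either an edge-list ``path`` or BA parameters
    ``ba: {n, m, m0}``.  All random stages derive their streams from the
    single master ``seed``.
    """

    network: dict
    seed: int = 0
    metrics: tuple[str, ...] = METRIC_NAMES
    lambda_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.3001, 0.02), 6))
    g_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.5001, 0.02), 6))
    lam_immunization: float = 0.15
    rho0: float = 0.05
    runs: int = 20
    dt: float = DEFAULT_DT
    t_max: float = DEFAULT_T_MAX
    burn_in: float = DEFAULT_BURN_IN
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("metrics", "lambda_grid", "g_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location is not part of the experiment
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def load_network(self) -> Network:
        if "path" in self.network:
            with open(self.network["path"]) as fh:
                return read_edge_list(fh)
        if "ba" in self.network:
            ba = self.network["ba"]
            return barabasi_albert(
                BAParams(n_nodes=ba["n"], m=ba["m"], m0=ba.get("m0"), seed=self.seed)
            )
        raise ValueError("network config needs a 'path' or 'ba' entry")


def _write_csv(df: pd.DataFrame, path: Path, config: ExperimentConfig) -> None:
    header = (
        f"# spreadrank {__version__} | config_hash={config.config_hash()} | seed={config.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def run(config: ExperimentConfig) -> dict:
    """Execute all experiment families and write CSV/JSON artifacts.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = config.load_network()
    ss = np.random.SeedSequence(config.seed)
    seed_spread, seed_imm = (int(c.generate_state(1, dtype=np.uint32)[0]) for c in ss.spawn(2))

    stats = topology_stats(net, exact_distances=net.n_nodes <= 3000, seed=config.seed)
    maxima = metric_maxima(net)

    spread = spreading_comparison(
        net, config.lambda_grid, rho0=config.rho0, runs=config.runs, seed=seed_spread,
        t_max=config.t_max, burn_in=config.burn_in, dt=config.dt, metrics=config.metrics,
    )
    _write_csv(spread.table, out / "spreading_comparison.csv", config)

    scan = threshold_scan(net, metrics=config.metrics)
    _write_csv(scan, out / "threshold_scan.csv", config)

    imm = immunization_comparison(
        net, lam=config.lam_immunization, rho0=config.rho0, g_grid=config.g_grid,
        runs=config.runs, seed=seed_imm, t_max=config.t_max, burn_in=config.burn_in,
        dt=config.dt,
    )
    _write_csv(imm.table, out / "immunization_comparison.csv", config)

    dd_table, dd_score = degree_distribution_report(net)
    _write_csv(dd_table, out / "degree_distribution.csv", config)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "topology": {
            "N": stats.N, "E": stats.E, "mean_degree": stats.mean_degree,
            "mean_distance": stats.mean_distance, "assortativity": stats.assortativity,
        },
        "metric_maxima": maxima,
        "closest_model_to_mc": spread.closest_model,
        "thresholds_theory": dict(zip(scan["metric"], scan["lambda_c_theory"])),
        "immunization_thresholds": imm.thresholds,
        "immunization_ranking": imm.ranking,
        "degree_loglog_r2": dd_score,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
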