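"""Benchmark statistics and surrogate diagnostics.

Benchmarking compares predicted against experimental property values with
RMSE (root-mean-square error) and MSD (mean signed deviation, a bias
measure), overall, per property type, and per functional group.  Confidence
intervals are percentile bootstrap intervals resampling whole molecules
(mixture pairs for binary data), not individual measurements, so that
repeated measurements of one substance are not treated as independent.

Surrogate diagnostics quantify how trustworthy a fitted surrogate ensemble
is: repeated bound-constrained local minimizations from random starts
measure the smoothness/multimodality of the surrogate landscape (SD_chi,
the standard deviation of the minimized objectives, and O_5%, the share of
starts finishing within 5% of the best minimum), and cross-validation
against independently found minima measures how far outside its own pool a
surrogate remains predictive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .optimize import local_minimize
from .parameter_space import BoundsBox, ParameterVector
from .property_data import TrainingSet
from .surrogate import SurrogateEnsemble, surrogate_objective, surrogate_objective_batch

__all__ = [
    "GroupStats",
    "BenchmarkReport",
    "RobustnessReport",
    "benchmark",
    "bootstrap_ci",
    "surrogate_robustness",
    "cross_validate_surrogates",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupStats:
    """RMSE/MSD (with bootstrap CIs) for one slice of the data."""

    scope: str                 # "overall" | "property_type" | "functional_group"
    name: str
    rmse: float
    msd: float
    n_measurements: int
    n_molecules: int
    rmse_ci: tuple[float, float] | None = None
    msd_ci: tuple[float, float] | None = None


@dataclass
class BenchmarkReport:
    overall: GroupStats
    per_type: dict[str, GroupStats]
    per_group: dict[str, GroupStats]

    def rows(self) -> list[GroupStats]:
        return [self.overall, *self.per_type.values(), *self.per_group.values()]


def _rmse(devs: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(devs))))


def _msd(devs: np.ndarray) -> float:
    return float(np.mean(devs))


def _stats_for(
    scope: str,
    name: str,
    by_molecule: dict[str, list[float]],
    n_boot: int,
    seed: int,
) -> GroupStats:
    devs = np.concatenate([np.atleast_1d(v) for v in by_molecule.values()])
    stats = GroupStats(
        scope=scope,
        name=name,
        rmse=_rmse(devs),
        msd=_msd(devs),
        n_measurements=devs.size,
        n_molecules=len(by_molecule),
    )
    if n_boot > 0:
        _, lo, hi = bootstrap_ci(by_molecule, _rmse, n_boot, seed)
        stats.rmse_ci = (lo, hi)
        _, lo, hi = bootstrap_ci(by_molecule, _msd, n_boot, seed + 1)
        stats.msd_ci = (lo, hi)
    return stats


def benchmark(
    predictions: Mapping[str, float],
    tset: TrainingSet,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> BenchmarkReport:
    """RMSE and MSD of predictions, overall / per type / per functional group.

    Functional-group slices use each measurement's first group tag (pure
    compounds) and the joined pair tag for binary measurements.  Empty
    slices are omitted with a logged warning.
    """
    overall: dict[str, list[float]] = {}
    by_type: dict[str, dict[str, list[float]]] = {}
    by_group: dict[str, dict[str, list[float]]] = {}
    for m in tset.measurements:
        if m.id not in predictions:
            logger.warning("benchmark: no prediction for %s; skipped", m.id)
            continue
        dev = predictions[m.id] - m.value
        mol = m.molecule
        overall.setdefault(mol, []).append(dev)
        by_type.setdefault(m.property_type, {}).setdefault(mol, []).append(dev)
        group = "+".join(m.functional_groups) if m.functional_groups else "untagged"
        by_group.setdefault(group, {}).setdefault(mol, []).append(dev)
    if not overall:
        raise ValueError("no overlapping measurements between predictions and set")
    return BenchmarkReport(
        overall=_stats_for("overall", "all", overall, n_boot, seed),
        per_type={
            t: _stats_for("property_type", t, groups, n_boot, seed + 10 + i)
            for i, (t, groups) in enumerate(sorted(by_type.items()))
        },
        per_group={
            g: _stats_for("functional_group", g, groups, n_boot, seed + 100 + i)
            for i, (g, groups) in enumerate(sorted(by_group.items()))
        },
    )


def bootstrap_ci(
    values_by_molecule: Mapping[str, float | Sequence[float]],
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI resampling molecules, not measurements.

    Returns (point estimate, 2.5th percentile, 97.5th percentile).  The
    statistic is applied to the pooled deviations of each resampled set of
    molecules; molecules are drawn with replacement.
    """
    if not values_by_molecule:
        raise ValueError("need at least one molecule")
    groups = [np.atleast_1d(np.asarray(v, dtype=float)) for v in values_by_molecule.values()]
    pooled = np.concatenate(groups)
    point = float(statistic(pooled))
    rng = np.random.default_rng(seed)
    n_mol = len(groups)
    sizes = {g.size for g in groups}
    if sizes == {1}:
        # common fast path: one deviation per molecule
        flat = np.concatenate(groups)
        idx = rng.integers(0, n_mol, size=(n_boot, n_mol))
        stats = np.array([statistic(flat[row]) for row in idx])
    else:
        stats = np.empty(n_boot)
        for b in range(n_boot):
            chosen = rng.integers(0, n_mol, size=n_mol)
            stats[b] = statistic(np.concatenate([groups[i] for i in chosen]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, float(lo), float(hi)


@dataclass
class RobustnessReport:
    """Smoothness metrics from repeated local minimization of a surrogate."""

    sd_chi: float              # SD of the minimized objectives
    pct_within_5: float        # % of starts within 5% of the best minimum
    n_starts: int
    pool_size: int             # K_sim: simulations behind the surrogate
    minima: np.ndarray = field(repr=False, default=None)


def surrogate_robustness(
    landscape: SurrogateEnsemble | Callable[[np.ndarray], float],
    tset: TrainingSet | None,
    bounds: BoundsBox,
    n_starts: int = 100,
    seed: int = 0,
) -> RobustnessReport:
    """Minimize the surrogate objective from random starts inside the bounds.

    ``landscape`` is either a fitted ensemble (with its training set) or any
    scalar objective over parameter arrays.  SD_chi near zero together with
    O_5% = 100 indicates a smooth, unimodal surrogate.
    """
    if isinstance(landscape, SurrogateEnsemble):
        if tset is None:
            raise ValueError("a training set is required with an ensemble")
        f = lambda x: float(surrogate_objective_batch(landscape, x.reshape(1, -1), tset)[0])
        pool_size = len(landscape.pool)
    else:
        f = lambda x: float(landscape(x))
        pool_size = 0
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = bounds.as_arrays()
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, lo.size))
    minima = np.array([local_minimize(f, x0, bounds)[1] for x0 in starts])
    best = minima.min()
    within = minima <= 1.05 * best if best > 0 else minima <= best + 1e-12
    return RobustnessReport(
        sd_chi=float(minima.std()),
        pct_within_5=float(100.0 * np.mean(within)),
        n_starts=n_starts,
        pool_size=pool_size,
        minima=minima,
    )


def cross_validate_surrogates(
    ensembles: Sequence[SurrogateEnsemble],
    minima: Sequence[tuple[ParameterVector, float]],
    tset: TrainingSet,
) -> np.ndarray:
    """Percent deviation of each surrogate's chi at each independent minimum.

    Entry (e, m) = 100 * (surrogate chi of ensemble e at theta_m - simulation
    chi_m) / simulation chi_m.  Minima with zero simulation chi yield NaN
    (deviation undefined).
    """
    out = np.full((len(ensembles), len(minima)), np.nan)
    for e, ensemble in enumerate(ensembles):
        for m, (theta, sim_chi) in enumerate(minima):
            surr = surrogate_objective(ensemble, theta, tset).chi
            if sim_chi == 0:
                continue
            out[e, m] = 100.0 * (surr - sim_chi) / sim_chi
    return out
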