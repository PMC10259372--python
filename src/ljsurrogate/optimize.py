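"""Differential-evolution search and the multi-fidelity optimization loop.

The outer loop alternates between two fidelities:

1. simulate an initial Latin-hypercube sample of parameter vectors (the
   baseline force field always included) and calibrate the objective
   scaling so chi(baseline) = 1;
2. fit one GP surrogate per measurement from all usable simulations, set
   search bounds from the pooled vectors expanded by eta, and run
   differential evolution on the surrogate-level objective;
3. evaluate the proposed vector at the simulation level; accept it iff its
   simulation chi beats the incumbent (the best accepted vector so far);
4. add the new simulation to the pool regardless of acceptance and rebuild;
5. if the surrogate search cannot beat the incumbent, rebuild with
   progressively stricter length-scale constraints (loose, then strict) and
   terminate when the strict level also fails;
6. otherwise stop at the iteration cap (or when an optional chi target is
   reached).

Every simulation-level evaluation therefore costs one evaluator call, and a
run's simulation budget is n_initial + (number of simulated iterations).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .objective import simulation_objective
from .parameter_space import (
    BoundsBox,
    ParameterSpace,
    ParameterVector,
    compute_bounds,
    lhs_initial_set,
)
from .property_data import (
    SimulationRecord,
    TrainingSet,
    calibrate_scaling,
    filter_for_surrogate,
)
from .seeding import derive_seed
from .surrogate import (
    TERMINATE,
    build_ensemble,
    escalate_constraints,
    surrogate_objective_batch,
)

__all__ = [
    "DESettings",
    "MultiFidelityConfig",
    "IterationRecord",
    "Trajectory",
    "EvaluatorError",
    "de_minimize",
    "local_minimize",
    "multi_fidelity_optimize",
]


class EvaluatorError(RuntimeError):
    """The simulation-level evaluator failed where failure is fatal."""


@dataclass
class DESettings:
    """Differential-evolution settings (SciPy defaults, stated explicitly)."""

    population_multiplier: int = 15      # population = multiplier * dimension
    mutation: tuple[float, float] = (0.5, 1.0)  # per-generation dithering
    recombination: float = 0.7
    convergence_tol: float = 0.01        # relative population-spread tolerance
    max_generations: int = 1000
    polish: bool = True                  # final L-BFGS-B refinement
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.recombination <= 1:
            raise ValueError("recombination must be in (0, 1]")
        lo, hi = self.mutation
        if not (0 <= lo <= hi <= 2):
            raise ValueError("mutation range must lie within [0, 2]")

    def population_size(self, dimension: int) -> int:
        return self.population_multiplier * dimension


def de_minimize(
    f: Callable[[np.ndarray], float],
    bounds: BoundsBox,
    settings: DESettings,
    *,
    batch_f: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[ParameterVector, float]:
    """Globally minimize f over the bounds box with differential evolution.

    ``f`` maps a parameter array (in the box's key order) to a scalar.  If
    ``batch_f`` is given (mapping an (n, d) matrix to an (n,) array) the DE
    generations are evaluated vectorized.  Deterministic for a fixed
    settings.seed; the returned vector always lies inside the bounds.
    """
    lo, hi = bounds.as_arrays()
    kwargs = dict(
        bounds=list(zip(lo, hi)),
        popsize=settings.population_multiplier,
        mutation=settings.mutation,
        recombination=settings.recombination,
        tol=settings.convergence_tol,
        maxiter=settings.max_generations,
        seed=settings.seed,
        polish=False,
        init="latinhypercube",
    )
    if batch_f is not None:
        result = differential_evolution(
            lambda x: batch_f(np.atleast_2d(np.asarray(x).T)),
            vectorized=True,
            updating="deferred",
            **kwargs,
        )
    else:
        result = differential_evolution(f, **kwargs)
    x_best, f_best = result.x, float(result.fun)
    if settings.polish:
        scalar = (lambda x: float(batch_f(x.reshape(1, -1))[0])) if batch_f else f
        res = minimize(scalar, x_best, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if res.fun < f_best:
            x_best, f_best = res.x, float(res.fun)
    x_best = np.clip(x_best, lo, hi)
    return ParameterVector.from_array(bounds.keys, x_best, label="de-proposal"), f_best


def local_minimize(
    f: Callable[[np.ndarray], float],
    start: ParameterVector | np.ndarray,
    bounds: BoundsBox,
) -> tuple[ParameterVector, float]:
    """Bound-constrained L-BFGS-B descent from start (finite-diff gradients)."""
    lo, hi = bounds.as_arrays()
    x0 = start.to_array(bounds.keys) if isinstance(start, ParameterVector) else np.asarray(start)
    x0 = np.clip(x0, lo, hi)
    f0 = float(f(x0))
    res = minimize(f, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
    if res.fun <= f0:
        x, fx = np.clip(res.x, lo, hi), float(res.fun)
    else:
        x, fx = x0, f0
    return ParameterVector.from_array(bounds.keys, x, label="local-min"), fx


# ---------------------------------------------------------------------------
# The outer loop

@dataclass
class MultiFidelityConfig:
    n_initial: int = 10
    eta: float = 1.1
    de: DESettings = field(default_factory=DESettings)
    gp_restarts: int = 5
    gp_normalize: bool = False
    gp_jitter: float = 1e-8
    gp_noise_variance: float | None = None
    max_iterations: int = 15
    escalate_on_repeated_rejection: bool = True
    chi_target: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["de"]["mutation"] = list(doc["de"]["mutation"])
        return doc


@dataclass
class IterationRecord:
    index: int
    proposal: ParameterVector
    surrogate_chi: float
    simulation_chi: float          # NaN if the evaluator failed / not simulated
    accepted: bool
    bounds: BoundsBox
    constraint_level: str
    pool_size: int
    simulated: bool = True

    def to_json(self) -> dict:
        return {
            "type": "iteration",
            "index": self.index,
            "proposal": {str(k): v for k, v in self.proposal.values.items()},
            "surrogate_chi": self.surrogate_chi,
            "simulation_chi": None if math.isnan(self.simulation_chi) else self.simulation_chi,
            "accepted": self.accepted,
            "bounds": {
                str(k): [self.bounds.lower[k], self.bounds.upper[k]]
                for k in self.bounds.keys
            },
            "constraint_level": self.constraint_level,
            "pool_size": self.pool_size,
            "simulated": self.simulated,
        }


@dataclass
class Trajectory:
    iterations: list[IterationRecord]
    best: tuple[ParameterVector, float]
    termination_reason: str
    n_initial: int = 0
    initial_chis: list[float] = field(default_factory=list)
    scaling: dict[str, float] = field(default_factory=dict)

    @property
    def n_simulations(self) -> int:
        """Total simulation-level evaluations: initial set plus iterations."""
        return self.n_initial + sum(1 for it in self.iterations if it.simulated)

    @property
    def accepted_chis(self) -> list[float]:
        return [it.simulation_chi for it in self.iterations if it.accepted]

    def write_jsonl(self, path: str | Path, config: MultiFidelityConfig | None = None) -> None:
        with open(path, "w") as fh:
            header = {
                "type": "header",
                "n_initial": self.n_initial,
                "initial_chis": self.initial_chis,
                "scaling": self.scaling,
                "termination_reason": self.termination_reason,
                "best_chi": self.best[1],
                "best_theta": {str(k): v for k, v in self.best[0].values.items()},
            }
            if config is not None:
                header["config"] = config.to_dict()
            fh.write(json.dumps(header) + "\n")
            for it in self.iterations:
                fh.write(json.dumps(it.to_json()) + "\n")


def _passes_filter(record: SimulationRecord, tset: TrainingSet) -> bool:
    return bool(filter_for_surrogate([record], tset))


def multi_fidelity_optimize(
    space: ParameterSpace,
    tset: TrainingSet,
    evaluator: Callable[[ParameterVector, TrainingSet], SimulationRecord],
    config: MultiFidelityConfig,
    *,
    stream_path: str | Path | None = None,
    log: Callable[[str], None] | None = None,
) -> Trajectory:
    """Run the full multi-fidelity optimization and return its trajectory."""
    seed = config.seed
    say = log or (lambda msg: None)

    # (1) initial design, simulated at full fidelity
    initial = lhs_initial_set(space, config.n_initial, derive_seed(seed, "lhs"))
    records = [evaluator(theta, tset) for theta in initial]
    if not records[0].ok:
        raise EvaluatorError("baseline evaluation failed; cannot calibrate scaling")
    tset = calibrate_scaling(tset, records[0])

    incumbent_theta = initial[0]
    incumbent_chi = simulation_objective(records[0], tset).chi  # = 1 by calibration
    initial_chis = [
        simulation_objective(r, tset).chi if r.ok else float("nan") for r in records
    ]

    pool: list[tuple[ParameterVector, SimulationRecord]] = [
        (theta, record)
        for theta, record in zip(initial, records)
        if _passes_filter(record, tset)
    ]
    say(f"initial sample: {len(initial)} vectors, {len(pool)} usable, chi(baseline)=1")

    iterations: list[IterationRecord] = []
    termination = "max_iterations"
    level = "none"
    consecutive_rejections = 0

    stream = open(stream_path, "w") if stream_path is not None else None
    try:
        if stream:
            stream.write(
                json.dumps({"type": "header", "config": config.to_dict()}) + "\n"
            )
        for index in range(config.max_iterations):
            # (2) surrogate build + global search, escalating constraints
            # within the iteration until the surrogate can beat the incumbent
            attempt_level = level
            proposal = None
            while True:
                thetas = [theta for theta, _record in pool]
                bounds = compute_bounds(thetas, config.eta)
                ensemble = build_ensemble(
                    pool,
                    tset,
                    attempt_level,
                    noise_variance=config.gp_noise_variance,
                    restarts=config.gp_restarts,
                    normalize=config.gp_normalize,
                    jitter=config.gp_jitter,
                    seed=derive_seed(seed, "gp", index, attempt_level),
                )
                de = dataclasses.replace(
                    config.de, seed=derive_seed(seed, "de", index, attempt_level)
                )
                batch = lambda X: surrogate_objective_batch(ensemble, X, tset)
                proposal, surr_chi = de_minimize(
                    lambda x: float(batch(x.reshape(1, -1))[0]),
                    bounds,
                    de,
                    batch_f=batch,
                )
                if surr_chi < incumbent_chi:
                    break
                nxt = escalate_constraints(attempt_level)
                say(
                    f"iter {index}: surrogate chi {surr_chi:.4g} >= incumbent "
                    f"{incumbent_chi:.4g}; escalating {attempt_level} -> {nxt}"
                )
                if nxt == TERMINATE:
                    iterations.append(
                        IterationRecord(
                            index=index,
                            proposal=proposal,
                            surrogate_chi=surr_chi,
                            simulation_chi=float("nan"),
                            accepted=False,
                            bounds=bounds,
                            constraint_level=attempt_level,
                            pool_size=len(pool),
                            simulated=False,
                        )
                    )
                    termination = "no_improvement_after_fallbacks"
                    break
                attempt_level = nxt
            if termination == "no_improvement_after_fallbacks":
                if stream:
                    stream.write(json.dumps(iterations[-1].to_json()) + "\n")
                break

            # (3) simulation-level validation of the proposal
            proposal.label = f"iteration-{index:03d}"
            record = evaluator(proposal, tset)
            if record.ok:
                sim_chi = simulation_objective(record, tset).chi
                accepted = sim_chi < incumbent_chi
            else:
                sim_chi = float("nan")
                accepted = False
                say(f"iter {index}: evaluator failed; proposal rejected")

            # (4) pool grows regardless of acceptance (failed/collapsed
            # records are filtered back out)
            if _passes_filter(record, tset):
                pool.append((proposal, record))

            if accepted:
                incumbent_theta, incumbent_chi = proposal, sim_chi
                level = "none"
                consecutive_rejections = 0
            else:
                consecutive_rejections += 1
                if (
                    config.escalate_on_repeated_rejection
                    and consecutive_rejections >= 2
                ):
                    nxt = escalate_constraints(level)
                    if nxt == TERMINATE:
                        termination = "no_improvement_after_fallbacks"
                    else:
                        level = nxt
                    consecutive_rejections = 0

            rec = IterationRecord(
                index=index,
                proposal=proposal,
                surrogate_chi=surr_chi,
                simulation_chi=sim_chi,
                accepted=accepted,
                bounds=bounds,
                constraint_level=attempt_level,
                pool_size=len(pool),
            )
            iterations.append(rec)
            if stream:
                stream.write(json.dumps(rec.to_json()) + "\n")
            say(
                f"iter {index}: surrogate chi {surr_chi:.4g}, simulation chi "
                f"{sim_chi:.4g}, accepted={accepted}, pool={len(pool)}, "
                f"level={attempt_level}"
            )

            if termination == "no_improvement_after_fallbacks":
                break
            if config.chi_target is not None and incumbent_chi <= config.chi_target:
                termination = "converged"
                break
    finally:
        if stream:
            stream.close()

    return Trajectory(
        iterations=iterations,
        best=(incumbent_theta, incumbent_chi),
        termination_reason=termination,
        n_initial=len(initial),
        initial_chis=initial_chis,
        scaling=dict(tset.scaling),
    )
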