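"""Scaled least-squares objective over physical-property residuals.

For N property types, each with M_n measurements, the fitness of a parameter
vector theta is

    chi(theta) = (1/N) * sum_n (1/M_n) * sum_m ((y_m(theta) - y_m) / d_n)^2

where y_m is the experimental value and d_n the per-type scaling
coefficient.  This is a ForceBalance-style weighted least squares with the
regularization (prior) term deliberately omitted, so chi depends only on the
residuals.  With d_n calibrated to the baseline's RMS deviation per type
(see :func:`ljsurrogate.property_data.calibrate_scaling`), every type
contributes exactly 1/N at the baseline and chi(baseline) = 1.

Predicted values may come directly from simulation-level records or from
surrogate-model predictions; the ``level`` field records which.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .property_data import SimulationRecord, TrainingSet, ValidationError

__all__ = ["ObjectiveEvaluation", "objective", "simulation_objective"]


@dataclass
class ObjectiveEvaluation:
    """chi and its per-property-type decomposition for one vector."""

    chi: float
    per_type: dict[str, float]
    level: str = "simulation"  # "simulation" | "surrogate"
    vector_label: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("simulation", "surrogate"):
            raise ValueError(f"level must be simulation/surrogate, got {self.level!r}")


def objective(
    predictions: Mapping[str, float],
    tset: TrainingSet,
    level: str = "simulation",
    vector_label: str = "",
) -> ObjectiveEvaluation:
    """Evaluate chi from a map of measurement id -> predicted value."""
    if not tset.scaling:
        raise ValidationError("training set scaling is not calibrated")
    types = tset.property_types
    n_types = len(types)
    per_type: dict[str, float] = {}
    for ptype in types:
        d_n = tset.scaling[ptype]
        measurements = tset.by_type(ptype)
        residuals = []
        for m in measurements:
            if m.id not in predictions:
                raise ValidationError(f"prediction missing for measurement {m.id!r}")
            residuals.append((predictions[m.id] - m.value) / d_n)
        contribution = float(np.mean(np.square(residuals))) / n_types
        per_type[ptype] = contribution
    return ObjectiveEvaluation(
        chi=float(sum(per_type.values())),
        per_type=per_type,
        level=level,
        vector_label=vector_label,
    )


def simulation_objective(record: SimulationRecord, tset: TrainingSet) -> ObjectiveEvaluation:
    """chi from a simulation-level record (must have status ok)."""
    if not record.ok:
        raise ValidationError(
            f"cannot evaluate objective of failed record {record.vector_label!r}"
        )
    return objective(
        record.values(), tset, level="simulation", vector_label=record.vector_label
    )
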