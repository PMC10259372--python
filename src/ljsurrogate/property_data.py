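"""Physical-property training sets and simulation records.

A training set is a list of experimental measurements of four property
types — pure-liquid density (g/mL), enthalpy of vaporization (kJ/mol),
binary-mixture density (g/mL), and enthalpy of mixing (kJ/mol) — each with
conditions, substance labels, and functional-group tags.  A simulation
record holds one evaluator run: predicted values (with uncertainties) for
every measurement at one parameter vector.

Two rules prepare records for surrogate building:

* records whose evaluation failed are omitted;
* records in which any predicted density falls strictly below 20% of the
  experimental value are omitted — such parameters have likely driven the
  system out of the liquid phase and carry no useful information about
  liquid densities.

Scaling coefficients ``d_n`` (one per property type) are calibrated from the
baseline force field's deviations so that every property type contributes
equally to the objective at the start of an optimization, and are then
frozen for the whole run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROPERTY_TYPES",
    "DENSITY_TYPES",
    "PROPERTY_UNITS",
    "DENSITY_EXCLUSION_FRACTION",
    "PropertyMeasurement",
    "TrainingSet",
    "Prediction",
    "SimulationRecord",
    "ValidationError",
    "read_training_set",
    "write_training_set",
    "filter_for_surrogate",
    "calibrate_scaling",
    "read_record_json",
    "write_record_json",
]

PROPERTY_TYPES = ("density_pure", "hvap", "density_binary", "hmix")
DENSITY_TYPES = ("density_pure", "density_binary")
PROPERTY_UNITS = {
    "density_pure": "g/mL",
    "density_binary": "g/mL",
    "hvap": "kJ/mol",
    "hmix": "kJ/mol",
}
_BINARY_TYPES = ("density_binary", "hmix")

#: Predicted densities strictly below this fraction of experiment flag a
#: likely phase change and exclude the whole record from surrogate building.
DENSITY_EXCLUSION_FRACTION = 0.20

_CSV_COLUMNS = [
    "id", "property_type", "component1", "component2", "x1", "x2",
    "temperature_K", "pressure_kPa", "value", "uncertainty", "units",
    "group1", "group2",
]


class ValidationError(ValueError):
    """A measurement or file violates the data contract."""


@dataclass
class PropertyMeasurement:
    """One experimental data point of the training or test set."""

    id: str
    property_type: str
    components: tuple[str, ...]
    mole_fractions: tuple[float, ...]
    temperature: float          # K
    pressure: float             # kPa
    value: float                # g/mL for densities, kJ/mol for enthalpies
    uncertainty: float
    functional_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.property_type not in PROPERTY_TYPES:
            raise ValidationError(
                f"measurement {self.id!r}: unknown property_type {self.property_type!r}"
            )
        expected = 2 if self.property_type in _BINARY_TYPES else 1
        if len(self.components) != expected:
            raise ValidationError(
                f"measurement {self.id!r}: {self.property_type} requires "
                f"{expected} component(s), got {len(self.components)}"
            )
        if expected == 2:
            if len(self.mole_fractions) != 2:
                raise ValidationError(
                    f"measurement {self.id!r}: binary entry needs two mole fractions"
                )
            if not math.isclose(sum(self.mole_fractions), 1.0, abs_tol=1e-6):
                raise ValidationError(
                    f"measurement {self.id!r}: mole fractions must sum to 1, "
                    f"got {self.mole_fractions}"
                )
        elif self.mole_fractions:
            raise ValidationError(
                f"measurement {self.id!r}: pure entry must not carry mole fractions"
            )
        if not math.isfinite(self.value):
            raise ValidationError(f"measurement {self.id!r}: non-finite value")

    @property
    def units(self) -> str:
        return PROPERTY_UNITS[self.property_type]

    @property
    def molecule(self) -> str:
        """Resampling unit for bootstraps: molecule, or pair for mixtures."""
        return "+".join(self.components)


@dataclass
class TrainingSet:
    """Measurements plus (once calibrated) per-type scaling coefficients."""

    measurements: list[PropertyMeasurement]
    scaling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValidationError("training set must contain at least one measurement")
        ids = [m.id for m in self.measurements]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate measurement ids in training set")
        for ptype, d in self.scaling.items():
            if d <= 0:
                raise ValidationError(f"scaling d_n for {ptype} must be positive")

    @property
    def property_types(self) -> tuple[str, ...]:
        """Distinct property types, in canonical order."""
        present = {m.property_type for m in self.measurements}
        return tuple(t for t in PROPERTY_TYPES if t in present)

    @property
    def n_types(self) -> int:
        return len(self.property_types)

    def by_type(self, property_type: str) -> list[PropertyMeasurement]:
        return [m for m in self.measurements if m.property_type == property_type]

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def get(self, measurement_id: str) -> PropertyMeasurement:
        for m in self.measurements:
            if m.id == measurement_id:
                return m
        raise KeyError(measurement_id)


@dataclass
class Prediction:
    value: float
    uncertainty: float = 0.0
    valid: bool = True


@dataclass
class SimulationRecord:
    """One evaluator run: predictions for every measurement at one vector."""

    vector_label: str
    predictions: dict[str, Prediction]
    status: str = "ok"  # "ok" | "failed"

    def __post_init__(self) -> None:
        if self.status not in ("ok", "failed"):
            raise ValidationError(f"record status must be ok/failed, got {self.status!r}")

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def values(self) -> dict[str, float]:
        return {mid: p.value for mid, p in self.predictions.items()}


# ---------------------------------------------------------------------------
# CSV I/O

def _blank(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""


def read_training_set(path: str | Path) -> TrainingSet:
    """Read a training set from CSV (columns documented in the module docs)."""
    try:
        frame = pd.read_csv(path, dtype={"id": str, "component1": str, "component2": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty training-set file") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise ValidationError(f"{path}: training set has no rows")
    measurements = []
    for idx, row in frame.iterrows():
        binary = row["property_type"] in _BINARY_TYPES
        components: tuple[str, ...]
        fractions: tuple[float, ...]
        if binary:
            if _blank(row["component2"]):
                raise ValidationError(f"{path} row {idx}: binary entry missing component2")
            components = (row["component1"], row["component2"])
            fractions = (float(row["x1"]), float(row["x2"]))
            groups = (str(row["group1"]), str(row["group2"]))
        else:
            components = (row["component1"],)
            fractions = ()
            groups = (str(row["group1"]),)
        try:
            measurements.append(
                PropertyMeasurement(
                    id=row["id"],
                    property_type=row["property_type"],
                    components=components,
                    mole_fractions=fractions,
                    temperature=float(row["temperature_K"]),
                    pressure=float(row["pressure_kPa"]),
                    value=float(row["value"]),
                    uncertainty=float(row["uncertainty"]),
                    functional_groups=groups,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    return TrainingSet(measurements)


def write_training_set(tset: TrainingSet, path: str | Path) -> None:
    rows = []
    for m in tset.measurements:
        binary = len(m.components) == 2
        rows.append(
            {
                "id": m.id,
                "property_type": m.property_type,
                "component1": m.components[0],
                "component2": m.components[1] if binary else "",
                "x1": m.mole_fractions[0] if binary else "",
                "x2": m.mole_fractions[1] if binary else "",
                "temperature_K": m.temperature,
                "pressure_kPa": m.pressure,
                "value": m.value,
                "uncertainty": m.uncertainty,
                "units": m.units,
                "group1": m.functional_groups[0] if m.functional_groups else "",
                "group2": m.functional_groups[1] if binary and len(m.functional_groups) > 1 else "",
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and scaling

def filter_for_surrogate(
    records: Sequence[SimulationRecord], tset: TrainingSet
) -> list[SimulationRecord]:
    """Drop failed records and records with a likely phase change.

    A record is excluded if any density-type prediction is *strictly* below
    ``DENSITY_EXCLUSION_FRACTION`` (20%) of the experimental value; a
    prediction exactly at the threshold is retained.  Order is preserved and
    the operation is idempotent.
    """
    density_ids = {
        m.id: m.value for m in tset.measurements if m.property_type in DENSITY_TYPES
    }
    kept = []
    for record in records:
        if not record.ok:
            continue
        collapsed = any(
            mid in record.predictions
            and record.predictions[mid].value < DENSITY_EXCLUSION_FRACTION * y_exp
            for mid, y_exp in density_ids.items()
        )
        if not collapsed:
            kept.append(record)
    return kept


def calibrate_scaling(tset: TrainingSet, baseline_record: SimulationRecord) -> TrainingSet:
    """Set d_n to the baseline RMS deviation of each property type.

    With the objective's (1/N)(1/M_n) normalization this makes every property
    type contribute exactly 1/N at the baseline, i.e. chi(baseline) = 1.
    Returns a new TrainingSet; scaling is then frozen for the run.
    """
    if not baseline_record.ok:
        raise ValidationError("cannot calibrate scaling from a failed baseline record")
    scaling: dict[str, float] = {}
    for ptype in tset.property_types:
        devs = []
        for m in tset.by_type(ptype):
            if m.id not in baseline_record.predictions:
                raise ValidationError(f"baseline record missing measurement {m.id!r}")
            devs.append(baseline_record.predictions[m.id].value - m.value)
        d_n = float(np.sqrt(np.mean(np.square(devs))))
        if d_n == 0.0:
            raise ValidationError(
                f"baseline reproduces {ptype} exactly; scaling coefficient would be zero"
            )
        scaling[ptype] = d_n
    return replace(tset, scaling=scaling)


# ---------------------------------------------------------------------------
# Record JSON

def write_record_json(record: SimulationRecord, path: str | Path) -> None:
    doc = {
        "vector_label": record.vector_label,
        "status": record.status,
        "predictions": {
            mid: {"value": p.value, "uncertainty": p.uncertainty, "valid": p.valid}
            for mid, p in record.predictions.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_record_json(path: str | Path) -> SimulationRecord:
    doc = json.loads(Path(path).read_text())
    predictions = {
        mid: Prediction(p["value"], p.get("uncertainty", 0.0), p.get("valid", True))
        for mid, p in doc["predictions"].items()
    }
    return SimulationRecord(doc["vector_label"], predictions, doc.get("status", "ok"))
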