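"""Simulation-level evaluator contract and a synthetic ground truth.

The optimization loop only requires a callable that maps a parameter vector
and a training set to a :class:`SimulationRecord` — in production that is a
molecular-dynamics property-estimation workflow.  This module supplies a
synthetic stand-in built around a planted optimum theta*: each measurement
responds smoothly (quadratically, in fractional parameter deviations) to a
known subset of the parameters, with additive Gaussian noise of the order
of typical simulation uncertainties and optional record-level failures.

The response of measurement m is

    y_m(theta) = y_m_exp * (1 + sum_i a_mi * s_i^2
                              + sum_ij b_mij * s_i * s_j
                              + ripple(s))  + eps,
    s_i = (theta_i - theta*_i) / theta*_i   for i in dep(m),

so predictions equal experiment exactly at theta* (noise aside) and the
global objective minimum sits at the planted optimum.  The optional cosine
ripple adds local minima to exercise global search.

Dependency maps are "segmented" the way real LJ refits are: hydrogen- and
carbon-type parameters are exercised by every compound, while each oxygen
type only affects the functional groups that contain it (ether oxygen only
ethers/esters, hydroxyl oxygen only alcohols, and so on).  Densities load
mainly on rmin_half curvature and enthalpies mainly on epsilon curvature;
the curvature magnitudes are chosen so that baseline deviations resemble a
typical starting force field (a few percent in density, 15-20% in enthalpy
of vaporization).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .parameter_space import ParameterKey, ParameterSpace, ParameterVector
from .property_data import (
    Prediction,
    PropertyMeasurement,
    SimulationRecord,
    TrainingSet,
)
from .seeding import derive_seed

__all__ = [
    "Evaluator",
    "SyntheticTruthSpec",
    "SyntheticEvaluator",
    "synthetic_evaluate",
    "make_pure_truth",
    "make_mixture_truth",
    "read_truth_spec",
    "write_truth_spec",
    "DEFAULT_NOISE_SD",
]

#: An evaluator is any callable (theta, training set) -> SimulationRecord
#: that is deterministic for a given theta and its own seed, and may return
#: a record with status="failed".
Evaluator = Callable[[ParameterVector, TrainingSet], SimulationRecord]

#: Default additive-noise standard deviations, the order of typical
#: simulation statistical uncertainties for these properties.
DEFAULT_NOISE_SD = {
    "density_pure": 0.003,     # g/mL
    "density_binary": 0.003,   # g/mL
    "hvap": 0.3,               # kJ/mol
    "hmix": 0.3,               # kJ/mol
}

#: SMIRKS types exercised by each functional group.  Hydrogen and
#: tetravalent carbon appear in every group; carbonyl-bearing groups add the
#: generic carbon/oxygen types; ether and hydroxyl oxygens are group-specific.
GROUP_SMIRKS = {
    "alkane": ("[#1:1]-[#6X4]", "[#6X4:1]"),
    "alcohol": ("[#1:1]-[#6X4]", "[#6X4:1]", "[#8X2H1+0:1]"),
    "ether": ("[#1:1]-[#6X4]", "[#6X4:1]", "[#8X2H0+0:1]"),
    "ester": ("[#1:1]-[#6X4]", "[#6X4:1]", "[#6:1]", "[#8:1]", "[#8X2H0+0:1]"),
    "ketone": ("[#1:1]-[#6X4]", "[#6X4:1]", "[#6:1]", "[#8:1]"),
}

_GROUP_CYCLE = ("alkane", "alcohol", "ether", "ester", "ketone")

# Curvature weights by (property class, attribute): densities respond mainly
# to atomic sizes (rmin_half), enthalpies mainly to well depths (epsilon).
_CURVATURE_WEIGHTS = {
    ("density", "rmin_half"): 8.0,
    ("density", "epsilon"): 0.5,
    ("enthalpy", "epsilon"): 9.0,
    ("enthalpy", "rmin_half"): 2.0,
}

# Wide initial ranges (notably the hydrogen epsilon at +/-50%) are attenuated
# so their absolute property response stays physical over the sampling box.
_WIDE_RANGE_REFERENCE = 0.1


@dataclass
class SyntheticTruthSpec:
    """Defines a synthetic ground-truth response surface with optimum theta*."""

    theta_star: ParameterVector
    dependency_map: dict[str, frozenset[ParameterKey]]
    curvature: dict[tuple[str, ParameterKey], float]
    cross_terms: dict[tuple[str, ParameterKey, ParameterKey], float] = field(
        default_factory=dict
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    failure_rate: float = 0.0
    seed: int = 0
    ripple_amplitude: float = 0.0
    ripple_period: float = 0.02  # in fractional-deviation units

    def __post_init__(self) -> None:
        for mid, deps in self.dependency_map.items():
            if not deps:
                raise ValueError(f"measurement {mid!r} depends on no parameters")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.failure_rate <= 1:
            raise ValueError("failure_rate must be a probability")


def _theta_rng(theta: ParameterVector, spec_seed: int) -> np.random.Generator:
    # Deterministic per (theta, spec): hash the exact float values so the
    # same vector always sees the same noise and failure draw.
    payload = theta.to_array().tobytes()
    return np.random.default_rng(
        np.random.SeedSequence([spec_seed, zlib.crc32(payload)])
    )


def synthetic_evaluate(
    theta: ParameterVector, tset: TrainingSet, spec: SyntheticTruthSpec
) -> SimulationRecord:
    """Evaluate the synthetic truth at theta and return a simulation record."""
    rng = _theta_rng(theta, spec.seed)
    label = theta.label or "theta"
    if spec.failure_rate > 0 and rng.random() < spec.failure_rate:
        return SimulationRecord(vector_label=label, predictions={}, status="failed")
    predictions: dict[str, Prediction] = {}
    for m in tset.measurements:
        deps = spec.dependency_map[m.id]
        s = {
            key: (theta[key] - spec.theta_star[key]) / spec.theta_star[key]
            for key in deps
        }
        response = sum(
            spec.curvature.get((m.id, key), 0.0) * s_i**2 for key, s_i in s.items()
        )
        for (mid, ki, kj), b in spec.cross_terms.items():
            if mid == m.id and ki in s and kj in s:
                response += b * s[ki] * s[kj]
        if spec.ripple_amplitude > 0:
            response += spec.ripple_amplitude * sum(
                1.0 - np.cos(2 * np.pi * s_i / spec.ripple_period)
                for s_i in s.values()
            )
        sd = spec.noise_sd.get(m.property_type, 0.0)
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        predictions[m.id] = Prediction(
            value=m.value * (1.0 + response) + noise, uncertainty=sd
        )
    return SimulationRecord(vector_label=label, predictions=predictions, status="ok")


@dataclass
class SyntheticEvaluator:
    """Callable evaluator bound to a training set's truth specification."""

    spec: SyntheticTruthSpec

    def __call__(self, theta: ParameterVector, tset: TrainingSet) -> SimulationRecord:
        return synthetic_evaluate(theta, tset, self.spec)


# ---------------------------------------------------------------------------
# Truth-set generators

def _draw_theta_star(space: ParameterSpace, rng: np.random.Generator) -> ParameterVector:
    lo, hi = space.initial_box()
    return ParameterVector.from_array(
        space.keys, rng.uniform(lo, hi), label="theta-star"
    )


def _range_half_width(space: ParameterSpace, key: ParameterKey) -> float:
    low, high = space.initial_ranges[key]
    return (high - low) / 200.0  # percentages -> fractional half-width


def _curvatures_for(
    measurement: PropertyMeasurement,
    deps: Sequence[ParameterKey],
    space: ParameterSpace,
    rng: np.random.Generator,
) -> dict[tuple[str, ParameterKey], float]:
    prop_class = (
        "density" if measurement.property_type.startswith("density") else "enthalpy"
    )
    out = {}
    for key in deps:
        w = _CURVATURE_WEIGHTS[(prop_class, key.attribute)]
        half_width = _range_half_width(space, key)
        attenuation = min(1.0, _WIDE_RANGE_REFERENCE / half_width)
        out[(measurement.id, key)] = float(rng.uniform(0.5, 1.5) * w * attenuation)
    return out


def make_pure_truth(
    space: ParameterSpace,
    n_compounds: int,
    seed: int,
    *,
    noise_sd: Mapping[str, float] | None = None,
    failure_rate: float = 0.0,
    ripple_amplitude: float = 0.0,
) -> tuple[TrainingSet, SyntheticTruthSpec]:
    """Pseudo pure-compound set: density and Hvap for each compound.

    Compounds cycle through the five functional groups; densities are drawn
    in 0.6-1.1 g/mL and vaporization enthalpies in 25-60 kJ/mol.  Each
    measurement depends on the epsilon and rmin_half keys of the SMIRKS
    types its group exercises.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "pure-truth"))
    theta_star = _draw_theta_star(space, rng)
    available = {k.smirks for k in space.keys}

    measurements: list[PropertyMeasurement] = []
    dependency_map: dict[str, frozenset[ParameterKey]] = {}
    curvature: dict[tuple[str, ParameterKey], float] = {}
    for c in range(n_compounds):
        group = _GROUP_CYCLE[c % len(_GROUP_CYCLE)]
        name = f"{group}-{c + 1:02d}"
        density = float(rng.uniform(0.6, 1.1))
        hvap = float(rng.uniform(25.0, 60.0))
        deps = tuple(
            ParameterKey(smirks, attribute)
            for smirks in GROUP_SMIRKS[group]
            if smirks in available
            for attribute in ("epsilon", "rmin_half")
        )
        if not deps:  # reduced space without this group's types
            deps = tuple(space.keys)
        for ptype, value, sd_default in (
            ("density_pure", density, 0.002),
            ("hvap", hvap, 0.2),
        ):
            m = PropertyMeasurement(
                id=f"{name}/{ptype}",
                property_type=ptype,
                components=(name,),
                mole_fractions=(),
                temperature=298.15,
                pressure=101.325,
                value=value,
                uncertainty=sd_default,
                functional_groups=(group,),
            )
            measurements.append(m)
            dependency_map[m.id] = frozenset(deps)
            curvature.update(_curvatures_for(m, deps, space, rng))

    tset = TrainingSet(measurements)
    spec = SyntheticTruthSpec(
        theta_star=theta_star,
        dependency_map=dependency_map,
        curvature=curvature,
        noise_sd=dict(noise_sd) if noise_sd is not None else dict(DEFAULT_NOISE_SD),
        failure_rate=failure_rate,
        seed=derive_seed(seed, "pure-noise"),
        ripple_amplitude=ripple_amplitude,
    )
    return tset, spec


def make_mixture_truth(
    space: ParameterSpace,
    n_pairs: int,
    seed: int,
    *,
    noise_sd: Mapping[str, float] | None = None,
    failure_rate: float = 0.0,
    ripple_amplitude: float = 0.0,
) -> tuple[TrainingSet, SyntheticTruthSpec]:
    """Pseudo binary-mixture set: rho(x) and Hmix(x) at up to 3 compositions.

    Each pair's dependency set is the union of the two components' group
    keys, so mixtures exercise more parameters than pure compounds.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "mixture-truth"))
    theta_star = _draw_theta_star(space, rng)
    available = {k.smirks for k in space.keys}
    groups = list(_GROUP_CYCLE)

    measurements: list[PropertyMeasurement] = []
    dependency_map: dict[str, frozenset[ParameterKey]] = {}
    curvature: dict[tuple[str, ParameterKey], float] = {}
    for p in range(n_pairs):
        g1 = groups[p % len(groups)]
        g2 = groups[(p + 1 + p // len(groups)) % len(groups)]
        c1, c2 = f"{g1}-{2 * p + 1:02d}", f"{g2}-{2 * p + 2:02d}"
        rho1, rho2 = rng.uniform(0.6, 1.1, size=2)
        hmix_scale = float(rng.uniform(0.2, 2.0)) * float(rng.choice([-1.0, 1.0]))
        smirks_union = tuple(
            dict.fromkeys(GROUP_SMIRKS[g1] + GROUP_SMIRKS[g2])
        )
        deps = tuple(
            ParameterKey(smirks, attribute)
            for smirks in smirks_union
            if smirks in available
            for attribute in ("epsilon", "rmin_half")
        )
        if not deps:
            deps = tuple(space.keys)
        for x1 in (0.25, 0.5, 0.75):
            x2 = 1.0 - x1
            rho_mix = float(x1 * rho1 + x2 * rho2)
            hmix = float(hmix_scale * 4.0 * x1 * x2)  # Margules-like shape
            for ptype, value, sd_default in (
                ("density_binary", rho_mix, 0.002),
                ("hmix", hmix, 0.2),
            ):
                m = PropertyMeasurement(
                    id=f"{c1}+{c2}/x{x1:.2f}/{ptype}",
                    property_type=ptype,
                    components=(c1, c2),
                    mole_fractions=(x1, x2),
                    temperature=298.15,
                    pressure=101.325,
                    value=value,
                    uncertainty=sd_default,
                    functional_groups=(g1, g2),
                )
                measurements.append(m)
                dependency_map[m.id] = frozenset(deps)
                curvature.update(_curvatures_for(m, deps, space, rng))

    tset = TrainingSet(measurements)
    spec = SyntheticTruthSpec(
        theta_star=theta_star,
        dependency_map=dependency_map,
        curvature=curvature,
        noise_sd=dict(noise_sd) if noise_sd is not None else dict(DEFAULT_NOISE_SD),
        failure_rate=failure_rate,
        seed=derive_seed(seed, "mixture-noise"),
        ripple_amplitude=ripple_amplitude,
    )
    return tset, spec


# ---------------------------------------------------------------------------
# Truth-spec serialization

def write_truth_spec(spec: SyntheticTruthSpec, path: str | Path) -> None:
    doc = {
        "theta_star": {str(k): v for k, v in spec.theta_star.values.items()},
        "dependency_map": {
            mid: sorted(str(k) for k in deps)
            for mid, deps in spec.dependency_map.items()
        },
        "curvature": [
            {"measurement": mid, "key": str(key), "a": a}
            for (mid, key), a in spec.curvature.items()
        ],
        "cross_terms": [
            {"measurement": mid, "key_i": str(ki), "key_j": str(kj), "b": b}
            for (mid, ki, kj), b in spec.cross_terms.items()
        ],
        "noise_sd": spec.noise_sd,
        "failure_rate": spec.failure_rate,
        "seed": spec.seed,
        "ripple_amplitude": spec.ripple_amplitude,
        "ripple_period": spec.ripple_period,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _parse_key(text: str) -> ParameterKey:
    smirks, _, attribute = text.rpartition(".")
    return ParameterKey(smirks, attribute)


def read_truth_spec(path: str | Path) -> SyntheticTruthSpec:
    doc = json.loads(Path(path).read_text())
    theta_star = ParameterVector(
        {_parse_key(k): float(v) for k, v in doc["theta_star"].items()},
        label="theta-star",
    )
    return SyntheticTruthSpec(
        theta_star=theta_star,
        dependency_map={
            mid: frozenset(_parse_key(k) for k in deps)
            for mid, deps in doc["dependency_map"].items()
        },
        curvature={
            (row["measurement"], _parse_key(row["key"])): float(row["a"])
            for row in doc["curvature"]
        },
        cross_terms={
            (row["measurement"], _parse_key(row["key_i"]), _parse_key(row["key_j"])): float(row["b"])
            for row in doc.get("cross_terms", [])
        },
        noise_sd=dict(doc["noise_sd"]),
        failure_rate=float(doc.get("failure_rate", 0.0)),
        seed=int(doc.get("seed", 0)),
        ripple_amplitude=float(doc.get("ripple_amplitude", 0.0)),
        ripple_period=float(doc.get("ripple_period", 0.02)),
    )
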