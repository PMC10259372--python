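"""Lennard-Jones parameter spaces, initial designs, and search bounds.

The optimization variable is a vector of LJ parameters: for each refitted
SMIRKS type, a well depth ``epsilon`` (kcal/mol) and a well-position
parameter ``rmin_half`` (Å, half the separation at the energy minimum).
SMIRKS strings are treated as opaque labels — no chemistry is performed on
them here.

The initial sampling region is a box expressed as percentages of a baseline
force field.  Initial designs are Latin hypercube samples over that box with
the baseline always included as the first vector.  During optimization the
search bounds are recomputed from the pool of already-simulated vectors:
per coordinate, ``upper = eta * max(pool)`` and ``lower = min(pool) / eta``,
with a small expansion factor ``eta >= 1`` so the optimizer can step outside
the sampled region.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ATTRIBUTES",
    "ParameterKey",
    "ParameterVector",
    "ParameterSpace",
    "BoundsBox",
    "ConfigurationError",
    "build_space",
    "default_space",
    "lhs_initial_set",
    "subsample_initial",
    "compute_bounds",
    "read_space_toml",
    "read_vector_json",
    "write_vector_json",
]

ATTRIBUTES = ("epsilon", "rmin_half")

#: Units of each attribute, used when serializing vectors.
UNITS = {"epsilon": "kcal/mol", "rmin_half": "angstrom"}


class ConfigurationError(ValueError):
    """A parameter-space definition is incomplete or inconsistent."""


@dataclass(frozen=True, order=True)
class ParameterKey:
    """One scalar optimization variable: (SMIRKS type, attribute)."""

    smirks: str
    attribute: str

    def __post_init__(self) -> None:
        if not self.smirks:
            raise ConfigurationError("SMIRKS pattern must be non-empty")
        if self.attribute not in ATTRIBUTES:
            raise ConfigurationError(
                f"attribute must be one of {ATTRIBUTES}, got {self.attribute!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.smirks}.{self.attribute}"


@dataclass
class ParameterVector:
    """An ordered assignment of strictly positive values to parameter keys."""

    values: dict[ParameterKey, float]
    label: str = ""

    def __post_init__(self) -> None:
        for key, value in self.values.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {key} must be strictly positive, got {value}")

    @property
    def keys(self) -> tuple[ParameterKey, ...]:
        return tuple(self.values)

    def to_array(self, keys: Sequence[ParameterKey] | None = None) -> np.ndarray:
        keys = self.keys if keys is None else keys
        return np.array([self.values[k] for k in keys], dtype=float)

    @classmethod
    def from_array(
        cls, keys: Sequence[ParameterKey], values: np.ndarray, label: str = ""
    ) -> "ParameterVector":
        return cls(dict(zip(keys, map(float, values))), label=label)

    def __getitem__(self, key: ParameterKey) -> float:
        return self.values[key]


@dataclass
class ParameterSpace:
    """The set of refitted keys, their baseline values, and initial ranges.

    ``initial_ranges`` maps each key to ``(low, high)`` percentages of the
    baseline value, e.g. ``(95, 105)`` for a ±5% initial box.
    """

    keys: list[ParameterKey]
    baseline: ParameterVector
    initial_ranges: dict[ParameterKey, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ConfigurationError("duplicate parameter keys in space")
        for key in self.keys:
            if key not in self.baseline.values:
                raise ConfigurationError(f"baseline value missing for {key}")
            if key not in self.initial_ranges:
                raise ConfigurationError(f"initial range missing for {key}")
            low, high = self.initial_ranges[key]
            if not 0 < low < high:
                raise ConfigurationError(
                    f"initial range for {key} must satisfy 0 < low < high, got ({low}, {high})"
                )

    @property
    def dimension(self) -> int:
        return len(self.keys)

    def initial_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Absolute (lower, upper) arrays of the initial sampling box."""
        base = self.baseline.to_array(self.keys)
        lows = np.array([self.initial_ranges[k][0] for k in self.keys]) / 100.0
        highs = np.array([self.initial_ranges[k][1] for k in self.keys]) / 100.0
        return base * lows, base * highs


@dataclass
class BoundsBox:
    """Axis-aligned search bounds, one interval per parameter key."""

    lower: dict[ParameterKey, float]
    upper: dict[ParameterKey, float]
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.eta < 1:
            raise ValueError(f"eta must be >= 1, got {self.eta}")
        for key in self.lower:
            if not self.lower[key] < self.upper[key]:
                raise ValueError(f"degenerate bounds for {key}")

    @property
    def keys(self) -> tuple[ParameterKey, ...]:
        return tuple(self.lower)

    def as_arrays(self, keys: Sequence[ParameterKey] | None = None):
        keys = self.keys if keys is None else keys
        lo = np.array([self.lower[k] for k in keys])
        hi = np.array([self.upper[k] for k in keys])
        return lo, hi

    def contains(self, theta: ParameterVector) -> bool:
        lo, hi = self.as_arrays()
        x = theta.to_array(self.keys)
        return bool(np.all(x >= lo) and np.all(x <= hi))


# ---------------------------------------------------------------------------
# Construction

def build_space(
    refit_table: Iterable[tuple[str, str]],
    baseline_values: Mapping[str, Mapping[str, float]],
    initial_ranges: Mapping[str, Mapping[str, tuple[float, float]]],
) -> ParameterSpace:
    """Build a ParameterSpace from a refit table plus per-type values/ranges.

    ``refit_table`` lists (smirks, description) pairs in presentation order;
    each type contributes two keys, epsilon before rmin_half, in table order.
    That ordering is fixed for the lifetime of the space and is the canonical
    serialization order.
    """
    smirks_seen: set[str] = set()
    keys: list[ParameterKey] = []
    base: dict[ParameterKey, float] = {}
    ranges: dict[ParameterKey, tuple[float, float]] = {}
    for smirks, _description in refit_table:
        if smirks in smirks_seen:
            raise ConfigurationError(f"SMIRKS type listed twice: {smirks}")
        smirks_seen.add(smirks)
        for attribute in ATTRIBUTES:
            key = ParameterKey(smirks, attribute)
            try:
                base[key] = float(baseline_values[smirks][attribute])
            except KeyError as exc:
                raise ConfigurationError(f"missing baseline value for {key}") from exc
            try:
                low, high = initial_ranges[smirks][attribute]
            except KeyError as exc:
                raise ConfigurationError(f"missing initial range for {key}") from exc
            ranges[key] = (float(low), float(high))
            keys.append(key)
    if not keys:
        raise ConfigurationError("refit table is empty")
    baseline = ParameterVector(base, label="baseline")
    return ParameterSpace(keys=keys, baseline=baseline, initial_ranges=ranges)


#: The six refitted SMIRKS types with OpenFF 1.0.0 LJ values, and the initial
#: sampling ranges (percent of baseline) used for the pure/mixture refits.
_DEFAULT_TABLE = [
    ("[#1:1]-[#6X4]", "Hydrogen attached to tetravalent carbon"),
    ("[#6:1]", "Generic carbon"),
    ("[#6X4:1]", "Tetravalent carbon"),
    ("[#8:1]", "Generic oxygen"),
    ("[#8X2H0+0:1]", "Divalent oxygen with no hydrogens attached"),
    ("[#8X2H1+0:1]", "Divalent oxygen with one hydrogen attached"),
]

_DEFAULT_BASELINE = {
    "[#1:1]-[#6X4]": {"epsilon": 0.0157, "rmin_half": 1.48698},
    "[#6:1]": {"epsilon": 0.0860, "rmin_half": 1.90800},
    "[#6X4:1]": {"epsilon": 0.1094, "rmin_half": 1.90800},
    "[#8:1]": {"epsilon": 0.2100, "rmin_half": 1.66120},
    "[#8X2H0+0:1]": {"epsilon": 0.1700, "rmin_half": 1.68370},
    "[#8X2H1+0:1]": {"epsilon": 0.2104, "rmin_half": 1.72100},
}

_DEFAULT_RANGES = {
    "[#1:1]-[#6X4]": {"epsilon": (50.0, 150.0), "rmin_half": (95.0, 105.0)},
    "[#6:1]": {"epsilon": (90.0, 110.0), "rmin_half": (95.0, 105.0)},
    "[#6X4:1]": {"epsilon": (90.0, 110.0), "rmin_half": (95.0, 105.0)},
    "[#8:1]": {"epsilon": (95.0, 105.0), "rmin_half": (95.0, 105.0)},
    "[#8X2H0+0:1]": {"epsilon": (95.0, 105.0), "rmin_half": (95.0, 105.0)},
    "[#8X2H1+0:1]": {"epsilon": (95.0, 105.0), "rmin_half": (95.0, 105.0)},
}


def default_space() -> ParameterSpace:
    """The 12-parameter space of the six refitted LJ SMIRKS types."""
    return build_space(_DEFAULT_TABLE, _DEFAULT_BASELINE, _DEFAULT_RANGES)


# ---------------------------------------------------------------------------
# Initial designs

def lhs_initial_set(space: ParameterSpace, n: int, seed: int) -> list[ParameterVector]:
    """Baseline plus an (n-1)-point Latin hypercube design over the initial box.

    Plain randomized LHS: per coordinate the n-1 equal-width strata of the
    initial range each receive exactly one sample, with an independent random
    permutation across coordinates.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = [ParameterVector(dict(space.baseline.values), label="baseline")]
    if n == 1:
        return out
    sampler = qmc.LatinHypercube(d=space.dimension, seed=seed)
    unit = sampler.random(n - 1)
    lo, hi = space.initial_box()
    samples = qmc.scale(unit, lo, hi)
    for i, row in enumerate(samples):
        out.append(ParameterVector.from_array(space.keys, row, label=f"lhs-{i:03d}"))
    return out


def subsample_initial(
    points: Sequence[ParameterVector], k: int, seed: int
) -> list[ParameterVector]:
    """Baseline plus ``k`` of the non-baseline points, without replacement."""
    if not points:
        raise ValueError("points must be non-empty")
    rest = list(points[1:])
    if k > len(rest):
        raise ValueError(f"cannot subsample {k} from {len(rest)} non-baseline points")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(rest), size=k, replace=False)
    return [points[0]] + [rest[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# Bounds

def compute_bounds(pool: Sequence[ParameterVector], eta: float) -> BoundsBox:
    """Search bounds from the pooled vectors: [min/eta, max*eta] per key."""
    if not pool:
        raise ValueError("pool must be non-empty")
    if eta < 1:
        raise ValueError(f"eta must be >= 1, got {eta}")
    keys = pool[0].keys
    arr = np.array([v.to_array(keys) for v in pool])
    lower = arr.min(axis=0) / eta
    upper = arr.max(axis=0) * eta
    # eta == 1 with a single vector would give a degenerate interval; nudge it
    # open so downstream optimizers always receive a valid box.
    degenerate = upper <= lower
    if np.any(degenerate):
        upper = upper.copy()
        upper[degenerate] = lower[degenerate] * (1 + 1e-12)
    return BoundsBox(
        lower=dict(zip(keys, map(float, lower))),
        upper=dict(zip(keys, map(float, upper))),
        eta=eta,
    )


# ---------------------------------------------------------------------------
# File formats

def read_space_toml(path: str | Path) -> ParameterSpace:
    """Read a parameter space from TOML (one ``[[type]]`` block per SMIRKS).

    Each block carries ``smirks``, optional ``description``, baseline
    ``epsilon`` / ``rmin_half``, and ``epsilon_range`` / ``rmin_half_range``
    as two-element percentage lists.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    blocks = doc.get("type")
    if not blocks:
        raise ConfigurationError(f"no [[type]] blocks in {path}")
    table, baseline, ranges = [], {}, {}
    for block in blocks:
        try:
            smirks = block["smirks"]
            table.append((smirks, block.get("description", "")))
            baseline[smirks] = {
                "epsilon": block["epsilon"],
                "rmin_half": block["rmin_half"],
            }
            ranges[smirks] = {
                "epsilon": tuple(block["epsilon_range"]),
                "rmin_half": tuple(block["rmin_half_range"]),
            }
        except KeyError as exc:
            raise ConfigurationError(f"incomplete [[type]] block in {path}: {exc}") from exc
    return build_space(table, baseline, ranges)


def write_vector_json(vector: ParameterVector, path: str | Path) -> None:
    by_smirks: dict[str, dict[str, float]] = {}
    for key, value in vector.values.items():
        by_smirks.setdefault(key.smirks, {})[key.attribute] = value
    doc = {"units": dict(UNITS), "label": vector.label, "values": by_smirks}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_vector_json(path: str | Path) -> ParameterVector:
    doc = json.loads(Path(path).read_text())
    values = {
        ParameterKey(smirks, attribute): float(value)
        for smirks, attrs in doc["values"].items()
        for attribute, value in attrs.items()
    }
    return ParameterVector(values, label=doc.get("label", ""))
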