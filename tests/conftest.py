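"""Shared fixtures: small parameter spaces and synthetic data sets."""

from __future__ import annotations

import pytest

import ljsurrogate as lj


@pytest.fixture(scope="session")
def space12():
    """The full 12-parameter space of the six refitted SMIRKS types."""
    return lj.default_space()


@pytest.fixture(scope="session")
def space4():
    """A reduced 4-parameter space (two SMIRKS types) for fast loop tests."""
    table = [
        ("[#6X4:1]", "Tetravalent carbon"),
        ("[#8X2H1+0:1]", "Divalent oxygen with one hydrogen attached"),
    ]
    baseline = {
        "[#6X4:1]": {"epsilon": 0.1094, "rmin_half": 1.908},
        "[#8X2H1+0:1]": {"epsilon": 0.2104, "rmin_half": 1.721},
    }
    ranges = {
        "[#6X4:1]": {"epsilon": (90.0, 110.0), "rmin_half": (95.0, 105.0)},
        "[#8X2H1+0:1]": {"epsilon": (95.0, 105.0), "rmin_half": (95.0, 105.0)},
    }
    return lj.build_space(table, baseline, ranges)


ZERO_NOISE = {t: 0.0 for t in lj.DEFAULT_NOISE_SD}


@pytest.fixture(scope="session")
def pure_truth_small(space4):
    """Noise-free 6-compound pure set on the reduced space."""
    return lj.make_pure_truth(space4, 6, seed=42, noise_sd=ZERO_NOISE)


@pytest.fixture(scope="session")
def calibrated_small(pure_truth_small):
    """(calibrated set, evaluator, baseline record) for the reduced space."""
    tset, spec = pure_truth_small
    evaluator = lj.SyntheticEvaluator(spec)
    baseline_record = None
    return tset, spec, evaluator


@pytest.fixture(scope="session")
def small_pool(space4, pure_truth_small):
    """A filtered, calibrated pool of 8 simulated vectors on the reduced space."""
    tset, spec = pure_truth_small
    evaluator = lj.SyntheticEvaluator(spec)
    vectors = lj.lhs_initial_set(space4, 8, seed=7)
    records = [evaluator(v, tset) for v in vectors]
    tset = lj.calibrate_scaling(tset, records[0])
    pairs = list(zip(vectors, records))
    return space4, tset, spec, pairs
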