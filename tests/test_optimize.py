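"""Differential evolution, local minimization, and the multi-fidelity loop."""

import json

import numpy as np
import pytest

import ljsurrogate as lj
from ljsurrogate.property_data import Prediction


def _box(keys, lo, hi, eta=1.0):
    return lj.BoundsBox(
        lower={k: float(l) for k, l in zip(keys, lo)},
        upper={k: float(h) for k, h in zip(keys, hi)},
        eta=eta,
    )


def _keys(n):
    smirks = ["[#6:1]", "[#8:1]", "[#6X4:1]", "[#1:1]-[#6X4]", "[#8X2H0+0:1]", "[#8X2H1+0:1]"]
    return [
        lj.ParameterKey(smirks[i // 2], ("epsilon", "rmin_half")[i % 2])
        for i in range(n)
    ]


class TestDEMinimize:
    def test_sphere_minimum_recovered_within_1e3_per_coordinate(self):
        keys = _keys(12)
        center = np.linspace(0.3, 0.8, 12)
        bounds = _box(keys, np.full(12, 0.1), np.full(12, 1.0))
        f = lambda x: float(np.sum((x - center) ** 2))
        best, value = lj.de_minimize(f, bounds, lj.DESettings(seed=1))
        assert np.all(np.abs(best.to_array(keys) - center) < 1e-3)
        assert value < 1e-6

    def test_generation_size_is_180_for_12_parameters(self):
        assert lj.DESettings().population_size(12) == 180

    def test_constant_function_returns_in_bounds_vector(self):
        keys = _keys(2)
        bounds = _box(keys, [0.0, 0.0], [1.0, 1.0])
        best, value = lj.de_minimize(
            lambda x: 7.5, bounds, lj.DESettings(seed=0, max_generations=5)
        )
        assert value == 7.5
        assert bounds.contains(best)

    def test_identical_seeds_give_identical_results(self):
        keys = _keys(3)
        bounds = _box(keys, [0.0] * 3, [1.0] * 3)
        f = lambda x: float(np.sum(np.sin(5 * x) + x**2))
        a = lj.de_minimize(f, bounds, lj.DESettings(seed=33, max_generations=40))
        b = lj.de_minimize(f, bounds, lj.DESettings(seed=33, max_generations=40))
        assert np.array_equal(a[0].to_array(keys), b[0].to_array(keys))
        assert a[1] == b[1]

    def test_vectorized_path_agrees_with_scalar_path(self):
        keys = _keys(2)
        center = np.array([0.4, 0.6])
        bounds = _box(keys, [0.0, 0.0], [1.0, 1.0])
        scalar = lambda x: float(np.sum((x - center) ** 2))
        batch = lambda X: np.sum((X - center) ** 2, axis=1)
        sb, sv = lj.de_minimize(scalar, bounds, lj.DESettings(seed=5))
        vb, vv = lj.de_minimize(scalar, bounds, lj.DESettings(seed=5), batch_f=batch)
        assert np.allclose(sb.to_array(keys), center, atol=1e-3)
        assert np.allclose(vb.to_array(keys), center, atol=1e-3)

    def test_mutation_outside_range_rejected(self):
        with pytest.raises(ValueError):
            lj.DESettings(mutation=(0.5, 2.5))


class TestLocalMinimize:
    def test_interior_quadratic_minimum_recovered(self):
        keys = _keys(3)
        center = np.array([0.5, 0.25, 0.75])
        bounds = _box(keys, [0.0] * 3, [1.0] * 3)
        f = lambda x: float(np.sum((x - center) ** 2))
        best, value = lj.local_minimize(f, np.array([0.9, 0.9, 0.1]), bounds)
        assert np.allclose(best.to_array(keys), center, atol=1e-6)

    def test_start_at_minimum_stays_there(self):
        keys = _keys(2)
        bounds = _box(keys, [0.0, 0.0], [1.0, 1.0])
        f = lambda x: float(np.sum((x - 0.5) ** 2))
        best, value = lj.local_minimize(f, np.array([0.5, 0.5]), bounds)
        assert np.allclose(best.to_array(keys), 0.5, atol=1e-8)

    def test_exterior_minimum_lands_on_the_box_face(self):
        keys = _keys(2)
        bounds = _box(keys, [0.0, 0.0], [1.0, 1.0])
        f = lambda x: float(np.sum((x - np.array([1.5, 0.5])) ** 2))
        best, _ = lj.local_minimize(f, np.array([0.2, 0.2]), bounds)
        x = best.to_array(keys)
        assert x[0] == pytest.approx(1.0, abs=1e-8)
        assert x[1] == pytest.approx(0.5, abs=1e-6)


ZERO_NOISE = {t: 0.0 for t in lj.DEFAULT_NOISE_SD}

FAST_LOOP = dict(
    gp_restarts=2,
    gp_noise_variance=1e-10,
    gp_jitter=1e-12,
)


@pytest.fixture(scope="module")
def small_zero_noise_run(space4):
    """A noise-free loop on the reduced space, shared across assertions."""
    tset, spec = lj.make_pure_truth(space4, 6, seed=42, noise_sd=ZERO_NOISE)
    evaluator = lj.SyntheticEvaluator(spec)
    config = lj.MultiFidelityConfig(
        n_initial=8,
        max_iterations=10,
        de=lj.DESettings(max_generations=120),
        seed=5,
        **FAST_LOOP,
    )
    trajectory = lj.multi_fidelity_optimize(space4, tset, evaluator, config)
    return space4, tset, spec, config, trajectory


class TestMultiFidelityLoop:
    def test_zero_noise_run_recovers_the_planted_optimum(self, small_zero_noise_run):
        space, _tset, spec, _config, trajectory = small_zero_noise_run
        best_theta, best_chi = trajectory.best
        assert best_chi < 0.1  # baseline chi is 1 by calibration
        star = spec.theta_star
        for key in space.keys:
            assert abs(best_theta[key] - star[key]) / star[key] < 0.02

    def test_accepted_chi_sequence_is_strictly_decreasing(self, small_zero_noise_run):
        *_rest, trajectory = small_zero_noise_run
        accepted = trajectory.accepted_chis
        assert len(accepted) >= 1
        assert all(b < a for a, b in zip(accepted, accepted[1:]))
        # and every accepted value beats the calibrated baseline
        assert all(c < 1.0 for c in accepted)

    def test_simulation_budget_is_initial_plus_iterations(self, small_zero_noise_run):
        _space, _tset, _spec, config, trajectory = small_zero_noise_run
        simulated = sum(1 for it in trajectory.iterations if it.simulated)
        assert trajectory.n_simulations == config.n_initial + simulated

    def test_bounds_follow_the_growing_pool(self, small_zero_noise_run):
        """Each iteration's DE box is the eta-expanded hull of the pool."""
        _space, _tset, _spec, config, trajectory = small_zero_noise_run
        for prev, nxt in zip(trajectory.iterations, trajectory.iterations[1:]):
            lo_p, hi_p = prev.bounds.as_arrays()
            lo_n, hi_n = nxt.bounds.as_arrays()
            assert np.all(lo_n <= lo_p + 1e-12) and np.all(hi_n >= hi_p - 1e-12)
        first = trajectory.iterations[0]
        assert first.bounds.eta == config.eta

    def test_trajectory_jsonl_has_header_and_iterations(
        self, small_zero_noise_run, tmp_path
    ):
        _space, _tset, _spec, config, trajectory = small_zero_noise_run
        path = tmp_path / "trajectory.jsonl"
        trajectory.write_jsonl(path, config)
        lines = [json.loads(line) for line in path.read_text().splitlines()]
        assert lines[0]["type"] == "header"
        assert lines[0]["config"]["n_initial"] == config.n_initial
        assert sum(1 for l in lines if l["type"] == "iteration") == len(
            trajectory.iterations
        )

    def test_flat_landscape_terminates_through_the_fallback_ladder(self, space4):
        tset, _spec = lj.make_pure_truth(space4, 4, seed=1, noise_sd=ZERO_NOISE)

        def flat_evaluator(theta, ts):
            # same (wrong) values for every theta: surrogate can never improve
            return lj.SimulationRecord(
                theta.label or "flat",
                {m.id: Prediction(m.value * 1.05) for m in ts.measurements},
            )

        config = lj.MultiFidelityConfig(
            n_initial=5,
            max_iterations=6,
            de=lj.DESettings(max_generations=20),
            seed=2,
            **FAST_LOOP,
        )
        trajectory = lj.multi_fidelity_optimize(space4, tset, flat_evaluator, config)
        assert trajectory.termination_reason == "no_improvement_after_fallbacks"
        assert trajectory.accepted_chis == []

    def test_failed_baseline_is_fatal(self, space4):
        tset, _spec = lj.make_pure_truth(space4, 4, seed=1)

        def failing(theta, ts):
            return lj.SimulationRecord(theta.label, {}, status="failed")

        config = lj.MultiFidelityConfig(n_initial=4, seed=0)
        with pytest.raises(lj.EvaluatorError, match="baseline"):
            lj.multi_fidelity_optimize(space4, tset, failing, config)

    def test_non_baseline_failures_are_tolerated(self, space4):
        tset, spec = lj.make_pure_truth(space4, 4, seed=7, noise_sd=ZERO_NOISE)
        inner = lj.SyntheticEvaluator(spec)
        calls = {"n": 0}

        def flaky(theta, ts):
            calls["n"] += 1
            if calls["n"] in (3, 5):  # fail two of the initial LHS points
                return lj.SimulationRecord(theta.label, {}, status="failed")
            return inner(theta, ts)

        config = lj.MultiFidelityConfig(
            n_initial=6,
            max_iterations=3,
            de=lj.DESettings(max_generations=30),
            seed=3,
            **FAST_LOOP,
        )
        trajectory = lj.multi_fidelity_optimize(space4, tset, flaky, config)
        assert trajectory.n_simulations == 6 + sum(
            1 for it in trajectory.iterations if it.simulated
        )
        assert trajectory.best[1] <= 1.0
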