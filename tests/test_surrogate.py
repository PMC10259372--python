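"""GP surrogate fitting, prediction, ensembles, and the constraint ladder."""

import numpy as np
import pytest

import ljsurrogate as lj
from ljsurrogate.surrogate import (
    TERMINATE,
    escalate_constraints,
    surrogate_objective_batch,
)

NOISE_FREE = dict(noise_variance=0.0, jitter=1e-12)


def _gp_oracle_predict(X, y, x_new, ls_grid, var_grid, noise=1e-10):
    """Brute-force GP refit: grid-search hyperparameters on the marginal
    likelihood, predict the posterior mean with plain linear algebra."""
    X = np.atleast_2d(X)
    mean = y.mean()
    yc = y - mean
    best = (None, -np.inf)
    for ls in ls_grid:
        for var in var_grid:
            d2 = (X[:, None, :] - X[None, :, :]) ** 2 / ls**2
            K = var * np.exp(-0.5 * d2.sum(-1)) + noise * np.eye(len(X))
            try:
                L = np.linalg.cholesky(K)
            except np.linalg.LinAlgError:
                continue
            alpha = np.linalg.solve(L.T, np.linalg.solve(L, yc))
            ll = (
                -0.5 * yc @ alpha
                - np.log(np.diag(L)).sum()
                - 0.5 * len(X) * np.log(2 * np.pi)
            )
            if ll > best[1]:
                best = ((ls, var, alpha), ll)
    ls, var, alpha = best[0]
    d2 = (np.atleast_2d(x_new)[:, None, :] - X[None, :, :]) ** 2 / ls**2
    k_star = var * np.exp(-0.5 * d2.sum(-1))
    return k_star @ alpha + mean


class TestFitGP:
    def test_constant_outputs_predict_the_constant(self):
        X = np.linspace(0, 1, 6).reshape(-1, 1)
        y = np.full(6, 3.7)
        model = lj.fit_gp(X, y, restarts=1, **NOISE_FREE)
        assert model.predict(np.array([0.31])) == pytest.approx(3.7, abs=1e-9)
        assert model.mean == pytest.approx(3.7)

    def test_noise_free_fit_interpolates_training_points(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 2, size=(8, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2
        model = lj.fit_gp(X, y, restarts=2, seed=1, **NOISE_FREE)
        for xi, yi in zip(X, y):
            assert model.predict(xi) == pytest.approx(yi, rel=1e-6, abs=1e-6)

    def test_quadratic_matches_brute_force_grid_refit(self):
        """ML-fitted GP is as accurate as an exhaustive hyperparameter grid."""
        X = np.linspace(-1, 1, 8).reshape(-1, 1)
        y = 2.0 * X[:, 0] ** 2 - 0.5 * X[:, 0] + 1.0
        x_new = np.linspace(-0.95, 0.95, 50).reshape(-1, 1)
        truth = 2.0 * x_new[:, 0] ** 2 - 0.5 * x_new[:, 0] + 1.0
        oracle = _gp_oracle_predict(
            X, y, x_new,
            ls_grid=np.geomspace(0.05, 5.0, 40),
            var_grid=np.geomspace(0.01, 100.0, 40),
        )
        oracle_err = np.abs(oracle - truth).max()
        model = lj.fit_gp(X, y, restarts=3, seed=0, **NOISE_FREE)
        fit_err = np.abs(model.predict(x_new) - truth).max()
        assert fit_err <= max(2 * oracle_err, 1e-8)

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            lj.fit_gp(np.array([[1.0]]), np.array([2.0]))

    def test_identical_rows_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(lj.SurrogateFitError):
            lj.fit_gp(X, np.array([1.0, 2.0, 3.0]))

    def test_fit_is_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(7, 3))
        y = rng.normal(size=7)
        a = lj.fit_gp(X, y, restarts=3, seed=9)
        b = lj.fit_gp(X, y, restarts=3, seed=9)
        assert np.array_equal(a.length_scales, b.length_scales)
        assert a.signal_variance == b.signal_variance
        assert a.noise_variance == b.noise_variance


class TestPredictLimits:
    @pytest.fixture
    def smooth_model(self):
        X = np.linspace(0, 1, 6).reshape(-1, 1)
        y = np.cos(3 * X[:, 0])
        return lj.fit_gp(X, y, restarts=2, seed=0, **NOISE_FREE)

    def test_far_outside_data_reverts_to_constant_mean(self, smooth_model):
        far = np.array([1e6])
        assert smooth_model.predict(far) == pytest.approx(smooth_model.mean, abs=1e-8)

    def test_symmetric_midpoint_predicts_symmetric_value(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([2.0, 2.0])
        model = lj.fit_gp(X, y, restarts=1, **NOISE_FREE)
        assert model.predict(np.array([0.0])) == pytest.approx(2.0, abs=1e-6)


class TestConstraintLevels:
    def test_levels_enforce_length_scale_floors(self, small_pool):
        _space, tset, _spec, pairs = small_pool
        for level, bound in (("loose", 1e-10), ("strict", 1e-5)):
            ensemble = lj.build_ensemble(
                pairs, tset, level, restarts=1, seed=2, **NOISE_FREE
            )
            min_ls = min(m.length_scales.min() for m in ensemble.models.values())
            assert min_ls > bound
            assert ensemble.constraint_level == level

    def test_escalation_ladder(self):
        assert escalate_constraints("none") == "loose"
        assert escalate_constraints("loose") == "strict"
        assert escalate_constraints("strict") == TERMINATE
        with pytest.raises(ValueError):
            escalate_constraints("bogus")


class TestEnsemble:
    def test_one_model_per_measurement_sharing_the_pool(self, small_pool):
        _space, tset, _spec, pairs = small_pool
        ensemble = lj.build_ensemble(pairs, tset, restarts=1, seed=0, **NOISE_FREE)
        assert set(ensemble.models) == {m.id for m in tset.measurements}
        for model in ensemble.models.values():
            assert model.inputs.shape[0] == len(pairs)

    def test_pool_below_two_rejected(self, small_pool):
        _space, tset, _spec, pairs = small_pool
        with pytest.raises(ValueError):
            lj.build_ensemble(pairs[:1], tset)

    def test_surrogate_chi_interpolates_simulation_chi_at_pool_vectors(self, small_pool):
        _space, tset, _spec, pairs = small_pool
        ensemble = lj.build_ensemble(pairs, tset, restarts=1, seed=0, **NOISE_FREE)
        for theta, record in pairs[:3]:
            surr = lj.surrogate_objective(ensemble, theta, tset).chi
            sim = lj.simulation_objective(record, tset).chi
            assert surr == pytest.approx(sim, rel=1e-6)
            assert surr >= 0

    def test_surrogate_chi_near_centroid_tracks_synthetic_truth(self, small_pool):
        space, tset, spec, pairs = small_pool
        ensemble = lj.build_ensemble(pairs, tset, restarts=2, seed=0, **NOISE_FREE)
        X = np.array([theta.to_array(space.keys) for theta, _ in pairs])
        centroid = lj.ParameterVector.from_array(space.keys, X.mean(axis=0))
        surr = lj.surrogate_objective(ensemble, centroid, tset).chi
        truth = lj.simulation_objective(
            lj.synthetic_evaluate(centroid, tset, spec), tset
        ).chi
        assert surr == pytest.approx(truth, rel=0.1, abs=0.02)

    def test_batch_objective_matches_scalar_path(self, small_pool):
        space, tset, _spec, pairs = small_pool
        ensemble = lj.build_ensemble(pairs, tset, restarts=1, seed=0, **NOISE_FREE)
        thetas = np.array([theta.to_array(space.keys) for theta, _ in pairs[:4]])
        batch = surrogate_objective_batch(ensemble, thetas, tset)
        for row, (theta, _) in zip(batch, pairs[:4]):
            assert row == pytest.approx(lj.surrogate_objective(ensemble, theta, tset).chi)

    def test_ensemble_determinism(self, small_pool):
        _space, tset, _spec, pairs = small_pool
        a = lj.build_ensemble(pairs, tset, restarts=2, seed=4)
        b = lj.build_ensemble(pairs, tset, restarts=2, seed=4)
        for mid in a.models:
            assert np.array_equal(a.models[mid].length_scales, b.models[mid].length_scales)

    def test_model_serialization_roundtrip_preserves_predictions(self, small_pool):
        space, tset, _spec, pairs = small_pool
        ensemble = lj.build_ensemble(pairs, tset, restarts=1, seed=0, **NOISE_FREE)
        mid, model = next(iter(ensemble.models.items()))
        rebuilt = lj.SurrogateModel.from_dict(model.to_dict())
        probe = pairs[2][0]
        assert rebuilt.predict(probe) == pytest.approx(model.predict(probe), rel=1e-8)
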