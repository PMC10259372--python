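"""Per-measurement Gaussian-process surrogates of physical properties.

One GP is fitted for every measurement in the training set, mapping the LJ
parameter vector to the simulated value of that measurement; the objective
is then assembled from the individual property predictions rather than
modelled directly.  Each GP uses a constant mean and an anisotropic RBF
kernel with one length scale per parameter (automatic relevance
determination); hyperparameters maximize the marginal likelihood via
multi-restart gradient ascent.  Predictions are the posterior mean only.

When an optimization iteration cannot improve on the incumbent, the
surrogates are rebuilt with a lower bound on the length scales — first a
loose bound (l > 1e-10), then a strict one (l > 1e-5) — because ARD
occasionally collapses a length scale to a degenerate value and ruins a
model.  If the strict level also fails, the optimization terminates.

Inputs and outputs are used in raw units by default; min-max input and
standardizing output normalization is available behind an opt-in flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .objective import ObjectiveEvaluation, objective
from .parameter_space import ParameterKey, ParameterVector
from .property_data import SimulationRecord, TrainingSet

__all__ = [
    "CONSTRAINT_LEVELS",
    "TERMINATE",
    "LENGTH_SCALE_BOUNDS",
    "SurrogateFitError",
    "SurrogateModel",
    "SurrogateEnsemble",
    "fit_gp",
    "build_ensemble",
    "surrogate_objective",
    "escalate_constraints",
]

CONSTRAINT_LEVELS = ("none", "loose", "strict")
TERMINATE = "terminate"

#: Lower bound imposed on every ARD length scale at each constraint level.
LENGTH_SCALE_BOUNDS = {"none": 0.0, "loose": 1e-10, "strict": 1e-5}

# Unconstrained fits still need a numerical floor for the log-scale optimizer.
_NUMERIC_FLOOR = 1e-15
_LENGTH_SCALE_CEIL = 1e4


class SurrogateFitError(RuntimeError):
    """GP hyperparameter fit failed even after jitter escalation."""


@dataclass
class SurrogateModel:
    """A fitted GP for one measurement."""

    measurement_id: str
    inputs: np.ndarray              # (n_pool, n_params), raw units
    outputs: np.ndarray             # (n_pool,)
    mean: float                     # fitted constant mean (output units)
    signal_variance: float
    length_scales: np.ndarray       # per parameter, raw units unless normalized
    noise_variance: float
    constraint_level: str = "none"
    normalize: bool = False
    keys: tuple[ParameterKey, ...] | None = None
    _gpr: GaussianProcessRegressor | None = field(default=None, repr=False)
    _x_lo: np.ndarray | None = field(default=None, repr=False)
    _x_span: np.ndarray | None = field(default=None, repr=False)
    _y_scale: float = field(default=1.0, repr=False)

    def predict(self, theta) -> float | np.ndarray:
        """Posterior mean at one vector or a (n, d) batch of vectors."""
        x = self._coerce(theta)
        if self._x_lo is not None:
            x = (x - self._x_lo) / self._x_span
        raw = self._gpr.predict(x)
        out = raw * self._y_scale + self.mean
        return float(out[0]) if out.shape[0] == 1 and np.ndim(theta) != 2 else out

    def _coerce(self, theta) -> np.ndarray:
        if isinstance(theta, ParameterVector):
            x = theta.to_array(self.keys)
        else:
            x = np.asarray(theta, dtype=float)
        return x.reshape(1, -1) if x.ndim == 1 else x

    def to_dict(self) -> dict:
        return {
            "measurement_id": self.measurement_id,
            "inputs": self.inputs.tolist(),
            "outputs": self.outputs.tolist(),
            "mean": self.mean,
            "signal_variance": self.signal_variance,
            "length_scales": self.length_scales.tolist(),
            "noise_variance": self.noise_variance,
            "constraint_level": self.constraint_level,
            "normalize": self.normalize,
            "keys": [[k.smirks, k.attribute] for k in self.keys] if self.keys else None,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SurrogateModel":
        keys = (
            tuple(ParameterKey(s, a) for s, a in doc["keys"]) if doc.get("keys") else None
        )
        return _refit_fixed(
            measurement_id=doc["measurement_id"],
            X=np.asarray(doc["inputs"], dtype=float),
            y=np.asarray(doc["outputs"], dtype=float),
            mean=doc["mean"],
            signal_variance=doc["signal_variance"],
            length_scales=np.asarray(doc["length_scales"], dtype=float),
            noise_variance=doc["noise_variance"],
            constraint_level=doc["constraint_level"],
            normalize=doc["normalize"],
            keys=keys,
        )


def _length_scale_bounds(constraint_level: str) -> tuple[float, float]:
    if constraint_level not in CONSTRAINT_LEVELS:
        raise ValueError(f"unknown constraint level {constraint_level!r}")
    floor = max(LENGTH_SCALE_BOUNDS[constraint_level], _NUMERIC_FLOOR)
    # keep the optimizer strictly above the stated threshold
    return (floor * (1 + 1e-6), _LENGTH_SCALE_CEIL)


def fit_gp(
    inputs: np.ndarray,
    outputs: np.ndarray,
    constraint_level: str = "none",
    *,
    noise_variance: float | None = None,
    restarts: int = 5,
    normalize: bool = False,
    jitter: float = 1e-8,
    seed: int = 0,
    measurement_id: str = "",
    keys: Sequence[ParameterKey] | None = None,
) -> SurrogateModel:
    """Fit a constant-mean ARD-RBF GP to (inputs, outputs).

    ``noise_variance=None`` infers a homoscedastic noise term (floored at
    ``jitter``); a float pins the noise to that value.  The fit is
    deterministic for a fixed ``seed``.  Ill-conditioned systems escalate the
    jitter a few times before raising :class:`SurrogateFitError`.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(outputs, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("GP fit requires at least 2 input rows")
    if np.unique(X, axis=0).shape[0] < 2:
        raise SurrogateFitError("all GP input rows are identical")

    x_lo = x_span = None
    y_scale = 1.0
    if normalize:
        x_lo = X.min(axis=0)
        x_span = np.where(np.ptp(X, axis=0) > 0, np.ptp(X, axis=0), 1.0)
        X = (X - x_lo) / x_span
        y_scale = float(y.std()) or 1.0

    mean = float(y.mean())
    yc = (y - mean) / y_scale

    ls_bounds = _length_scale_bounds(constraint_level)
    spans = X.std(axis=0)
    ls0 = np.where(spans > 0, spans, 1.0)
    ls0 = np.clip(ls0, ls_bounds[0] * 10, ls_bounds[1] / 10)
    var0 = float(yc.var()) or 1.0

    kernel = ConstantKernel(var0, (1e-12, 1e8)) * RBF(ls0, [ls_bounds] * X.shape[1])
    if noise_variance is None:
        noise_upper = max(float(yc.var()), jitter * 10)
        kernel = kernel + WhiteKernel(
            min(jitter * 10, noise_upper), (jitter, noise_upper)
        )
        alpha = jitter
    else:
        alpha = max(noise_variance, jitter)

    current_alpha = alpha
    last_error: Exception | None = None
    for _attempt in range(5):
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            alpha=current_alpha,
            normalize_y=False,
            n_restarts_optimizer=restarts,
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                gpr.fit(X, yc)
            break
        except np.linalg.LinAlgError as exc:
            last_error = exc
            current_alpha *= 100.0
    else:
        raise SurrogateFitError(
            f"GP fit for {measurement_id!r} remained ill-conditioned "
            f"after jitter escalation"
        ) from last_error

    fitted = gpr.kernel_
    if noise_variance is None:
        signal_var = float(fitted.k1.k1.constant_value)
        length_scales = np.atleast_1d(np.asarray(fitted.k1.k2.length_scale, dtype=float))
        fit_noise = float(fitted.k2.noise_level) * y_scale**2
    else:
        signal_var = float(fitted.k1.constant_value)
        length_scales = np.atleast_1d(np.asarray(fitted.k2.length_scale, dtype=float))
        fit_noise = float(noise_variance)

    return SurrogateModel(
        measurement_id=measurement_id,
        inputs=np.asarray(inputs, dtype=float),
        outputs=y,
        mean=mean,
        signal_variance=signal_var * y_scale**2,
        length_scales=length_scales,
        noise_variance=fit_noise,
        constraint_level=constraint_level,
        normalize=normalize,
        keys=tuple(keys) if keys is not None else None,
        _gpr=gpr,
        _x_lo=x_lo,
        _x_span=x_span,
        _y_scale=y_scale,
    )


def _refit_fixed(
    measurement_id, X, y, mean, signal_variance, length_scales, noise_variance,
    constraint_level, normalize, keys,
) -> SurrogateModel:
    """Rebuild a model from stored hyperparameters without re-optimizing."""
    x_lo = x_span = None
    y_scale = 1.0
    Xf = X
    if normalize:
        x_lo = X.min(axis=0)
        x_span = np.where(np.ptp(X, axis=0) > 0, np.ptp(X, axis=0), 1.0)
        Xf = (X - x_lo) / x_span
        y_scale = float(y.std()) or 1.0
    yc = (y - mean) / y_scale
    kernel = ConstantKernel(
        signal_variance / y_scale**2, "fixed"
    ) * RBF(length_scales, "fixed")
    gpr = GaussianProcessRegressor(
        kernel=kernel, alpha=max(noise_variance / y_scale**2, 1e-12), optimizer=None
    )
    gpr.fit(Xf, yc)
    return SurrogateModel(
        measurement_id=measurement_id,
        inputs=X,
        outputs=y,
        mean=mean,
        signal_variance=signal_variance,
        length_scales=length_scales,
        noise_variance=noise_variance,
        constraint_level=constraint_level,
        normalize=normalize,
        keys=keys,
        _gpr=gpr,
        _x_lo=x_lo,
        _x_span=x_span,
        _y_scale=y_scale,
    )


@dataclass
class SurrogateEnsemble:
    """One GP per training measurement, all sharing the same simulation pool."""

    models: dict[str, SurrogateModel]
    pool: list[tuple[ParameterVector, SimulationRecord]]
    constraint_level: str = "none"

    @property
    def keys(self) -> tuple[ParameterKey, ...]:
        return self.pool[0][0].keys

    def predict_all(self, theta) -> dict[str, float]:
        return {mid: model.predict(theta) for mid, model in self.models.items()}

    def predict_matrix(self, thetas: np.ndarray) -> dict[str, np.ndarray]:
        """Batch prediction: (n, d) matrix -> per-measurement value arrays."""
        return {mid: model.predict(thetas) for mid, model in self.models.items()}

    def to_dict(self) -> dict:
        return {
            "constraint_level": self.constraint_level,
            "models": {mid: m.to_dict() for mid, m in self.models.items()},
        }


def build_ensemble(
    pool: Sequence[tuple[ParameterVector, SimulationRecord]],
    tset: TrainingSet,
    constraint_level: str = "none",
    *,
    noise_variance: float | None = None,
    restarts: int = 5,
    normalize: bool = False,
    jitter: float = 1e-8,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Fit one GP per measurement from the filtered simulation pool."""
    if len(pool) < 2:
        raise ValueError("ensemble construction requires at least 2 pooled vectors")
    keys = pool[0][0].keys
    X = np.array([theta.to_array(keys) for theta, _record in pool])
    models: dict[str, SurrogateModel] = {}
    for index, m in enumerate(tset.measurements):
        y = np.array([record.predictions[m.id].value for _theta, record in pool])
        models[m.id] = fit_gp(
            X,
            y,
            constraint_level,
            noise_variance=noise_variance,
            restarts=restarts,
            normalize=normalize,
            jitter=jitter,
            seed=seed + index,
            measurement_id=m.id,
            keys=keys,
        )
    return SurrogateEnsemble(models=models, pool=list(pool), constraint_level=constraint_level)


def surrogate_objective(
    ensemble: SurrogateEnsemble, theta: ParameterVector, tset: TrainingSet
) -> ObjectiveEvaluation:
    """chi assembled from the per-measurement surrogate predictions."""
    predictions = ensemble.predict_all(theta)
    return objective(predictions, tset, level="surrogate", vector_label=theta.label)


def surrogate_objective_batch(
    ensemble: SurrogateEnsemble, thetas: np.ndarray, tset: TrainingSet
) -> np.ndarray:
    """Vectorized chi over an (n, d) matrix of candidate vectors."""
    thetas = np.asarray(thetas, dtype=float)
    preds = ensemble.predict_matrix(thetas)
    n_types = tset.n_types
    chi = np.zeros(thetas.shape[0])
    for ptype in tset.property_types:
        d_n = tset.scaling[ptype]
        members = tset.by_type(ptype)
        sq = np.zeros(thetas.shape[0])
        for m in members:
            sq += ((preds[m.id] - m.value) / d_n) ** 2
        chi += sq / (len(members) * n_types)
    return chi


def escalate_constraints(level: str) -> str:
    """Next rung of the length-scale fallback ladder (strict -> terminate)."""
    ladder = {"none": "loose", "loose": "strict", "strict": TERMINATE}
    if level not in ladder:
        raise ValueError(f"unknown constraint level {level!r}")
    return ladder[level]
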