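"""Gaussian-process surrogates over the encoded reaction space.

One probabilistic regressor is fitted per objective. The optimizer is a
minimizer, so percentage objectives are transformed to losses as
``loss = 100 - value`` before fitting; predictions are back-transformed
for reporting. The kernel is an anisotropic Matérn 5/2 with a fitted
white-noise term; ordinal parameters are treated as continuous after
integer encoding, matching the integer representation used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .space import Conditions, ReactionSpace, encode

__all__ = [
    "ObjectiveSpec",
    "SurrogateModel",
    "transform_objective",
    "inverse_transform",
    "objective_value",
    "fit_surrogate",
    "predict",
    "YIELD",
    "BETA_SELECTIVITY",
    "ALPHA_SELECTIVITY",
]


def transform_objective(value: float) -> float:
    """Percentage objective -> minimizer loss, ``100 - value``.

    Values above 100 (NMR integration error, e.g. a 101% yield) are not
    clamped; they simply give a small negative loss.
    """
    return 100.0 - value


def inverse_transform(loss: float) -> float:
    """Loss -> percentage objective; exact inverse of the transform."""
    return 100.0 - loss


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which percentage an optimizer maximizes, and how it is measured.

    ``name`` is one of ``yield``, ``beta_selectivity``,
    ``alpha_selectivity``. All objectives are maximized after the
    ``100 - value`` loss transform.
    """

    name: str

    def __post_init__(self):
        if self.name not in ("yield", "beta_selectivity", "alpha_selectivity"):
            raise ValueError(f"unknown objective {self.name!r}")


YIELD = ObjectiveSpec("yield")
BETA_SELECTIVITY = ObjectiveSpec("beta_selectivity")
ALPHA_SELECTIVITY = ObjectiveSpec("alpha_selectivity")


def objective_value(spec: ObjectiveSpec, yield_pct: float, beta_pct: float) -> float:
    """Extract an objective's percentage value from a measured outcome.

    The anomer ratio is a fraction of product formed: when the yield is
    zero there is no product and hence no anomer of either kind, so both
    selectivities are 0 for failed reactions rather than alpha defaulting
    to ``100 - 0``. For productive reactions alpha% = 100 - beta%.
    """
    if spec.name == "yield":
        return yield_pct
    if spec.name == "beta_selectivity":
        return beta_pct
    return 100.0 - beta_pct if yield_pct > 0 else 0.0


@dataclass
class SurrogateModel:
    """A fitted GP regressor plus the encoding it was trained under."""

    space: ReactionSpace
    objective: ObjectiveSpec
    gp: GaussianProcessRegressor
    X_train: np.ndarray
    y_train: np.ndarray  # losses
    seed: int

    def _scale(self, X: np.ndarray) -> np.ndarray:
        """Min-max scale each encoded axis to [0, 1] over its domain."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo = np.array([self.space.axis_range(p)[0] for p in self.space.parameters])
        hi = np.array([self.space.axis_range(p)[1] for p in self.space.parameters])
        return (X - lo) / (hi - lo)

    def predict_encoded(self, X: np.ndarray, return_std: bool = False):
        """Predict mean loss (and optionally sd) at encoded vectors."""
        return self.gp.predict(self._scale(X), return_std=return_std)


def fit_surrogate(
    observations: Sequence[tuple[Conditions, float]],
    spec: ObjectiveSpec,
    space: ReactionSpace,
    seed: int = 0,
    n_restarts: int = 1,
) -> SurrogateModel:
    """Fit a GP to (conditions, objective %) observations.

    Hyperparameters come from marginal-likelihood optimization with a
    fixed restart count and seed, so refits on identical data are
    bit-reproducible.
    """
    if len(observations) < 2:
        raise ValueError(
            "need at least 2 observations to fit a surrogate; "
            "use random sampling to initiate the campaign"
        )
    X = np.array([encode(space, c) for c, _ in observations])
    y = np.array([transform_objective(v) for _, v in observations])
    d = X.shape[1]
    # axes are scaled to [0, 1]; a length scale beyond ~3 there is already
    # indistinguishable from a flat/linear axis, so the bounds keep every
    # declared parameter active instead of letting the marginal likelihood
    # prune axes outright
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.full(d, 0.5), length_scale_bounds=(0.05, 3.0), nu=2.5)
        + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-8, 1e1))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=int(seed) % (2**31),
        alpha=1e-10,
    )
    model = SurrogateModel(space, spec, gp, X, y, int(seed))
    with warnings.catch_warnings():
        # hitting a deliberately tight length-scale bound is expected
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(model._scale(X), y)
    return model


def predict(model: SurrogateModel, c: Conditions) -> tuple[float, float]:
    """Mean loss and standard deviation at one set of conditions."""
    x = encode(model.space, c)  # raises on invalid conditions
    mean, sd = model.predict_encoded(x[None, :], return_std=True)
    return float(mean[0]), float(sd[0])
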