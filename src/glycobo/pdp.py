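"""Partial dependence of surrogate predictions on single parameters.

A partial dependence curve shows the average predicted objective as one
parameter sweeps its range while every other parameter is averaged over a
background sample (by default the conditions the model was trained on —
i.e. trends are inferred from the campaign's own data). It is the
surrogate-based analogue of a one-variable-at-a-time scan.

Discrete parameters are evaluated only at their registered integer
levels; plotting may interpolate between them for display, but values
between levels carry no physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import Conditions, ReactionSpace
from .surrogate import SurrogateModel, inverse_transform

__all__ = ["PDPCurve", "partial_dependence", "pdp_table"]


@dataclass(frozen=True)
class PDPCurve:
    parameter: str
    grid: tuple          # native-unit grid values, ascending
    response: tuple      # predicted objective (%), back-transformed
    objective: str

    def __post_init__(self):
        if list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be ascending")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response")


def partial_dependence(
    model: SurrogateModel,
    space: ReactionSpace,
    parameter: str,
    grid_size: int = 25,
    background: list[Conditions] | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PDPCurve:
    """Average-prediction curve for one parameter.

    ``background`` may be a list of conditions or an already-encoded
    matrix; it defaults to the model's training inputs. The response is
    reported on the objective's percentage scale (back-transformed from
    the loss the model predicts).
    """
    spec = space.spec(parameter)  # KeyError if unknown
    axis = space.names.index(parameter)
    if background is None:
        B = np.array(model.X_train, dtype=float, copy=True)
    elif isinstance(background, np.ndarray):
        B = np.array(background, dtype=float, copy=True)
    else:
        from .space import encode
        B = np.array([encode(space, c) for c in background])
    if spec.is_continuous:
        lo, hi = spec.bounds
        grid = np.linspace(lo, hi, grid_size)
        axis_vals = (grid - lo) / (hi - lo)
    else:
        grid = np.array(sorted(spec.codes), dtype=float)
        axis_vals = grid
    responses = []
    for g in axis_vals:
        Bg = B.copy()
        Bg[:, axis] = g
        mean_loss = float(np.mean(model.predict_encoded(Bg)))
        responses.append(inverse_transform(mean_loss))
    return PDPCurve(parameter, tuple(float(g) for g in grid),
                    tuple(responses), model.objective.name)


def pdp_table(curves: list[PDPCurve]) -> pd.DataFrame:
    """Tidy (parameter, grid value, objective, response) table."""
    rows = [
        {"parameter": c.parameter, "grid_value": g,
         "objective": c.objective, "response_pct": r}
        for c in curves for g, r in zip(c.grid, c.response)
    ]
    return pd.DataFrame(rows)
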