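"""Campaign-level analytics: objective points, contribution tables,
fronts and convergence, assembled from experiment records."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .campaign_io import ExperimentResult
from .hypervolume import (
    FrontResult,
    ObjectivePoint,
    hv_convergence,
    pareto_front,
    point_hypervolume,
    round_half_away,
    total_hypervolume,
)
from .surrogate import ALPHA_SELECTIVITY, BETA_SELECTIVITY, objective_value

__all__ = ["campaign_points", "contribution_table", "campaign_front",
           "campaign_convergence"]

_SPECS = {"beta": BETA_SELECTIVITY, "alpha": ALPHA_SELECTIVITY}


def campaign_points(results: Sequence[ExperimentResult],
                    objective: str = "beta") -> list[ObjectivePoint]:
    """(yield, selectivity) points for a campaign under one objective pair.

    ``objective`` picks the selectivity axis: ``beta`` uses the β-anomer
    percentage, ``alpha`` its complement on product (0 for failed
    reactions).
    """
    spec = _SPECS[objective]
    return [
        ObjectivePoint(r.yield_pct,
                       objective_value(spec, r.yield_pct, r.beta_pct))
        for r in results if not r.pending
    ]


def contribution_table(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Per-experiment hypervolume contributions, recomputed from outcomes.

    One row per completed experiment with the rectangle-area contribution
    under both selectivity readings, plus the nearest-integer values the
    campaign tables print.
    """
    rows = []
    for r in results:
        if r.pending:
            continue
        hv_b = point_hypervolume(ObjectivePoint(
            r.yield_pct, objective_value(_SPECS["beta"], r.yield_pct, r.beta_pct)))
        hv_a = point_hypervolume(ObjectivePoint(
            r.yield_pct, objective_value(_SPECS["alpha"], r.yield_pct, r.beta_pct)))
        rows.append({
            "Exp": r.exp_no, "YieldPct": r.yield_pct, "BetaPct": r.beta_pct,
            "HVContrBeta": hv_b, "HVContrBetaInt": round_half_away(hv_b),
            "HVContrAlpha": hv_a, "HVContrAlphaInt": round_half_away(hv_a),
        })
    return pd.DataFrame(rows)


def campaign_front(results: Sequence[ExperimentResult],
                   objective: str = "beta") -> FrontResult:
    return pareto_front(campaign_points(results, objective))


def campaign_convergence(results: Sequence[ExperimentResult],
                         objective: str = "beta") -> list[float]:
    """Cumulative total hypervolume after each batch of a campaign."""
    done = [r for r in results if not r.pending]
    if any(r.batch is None for r in done):
        raise ValueError("missing batch labels")
    return hv_convergence(campaign_points(done, objective),
                          [r.batch for r in done])
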