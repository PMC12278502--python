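"""Campaign figures: per-experiment contributions with the running total
hypervolume, objective-plane scatter with the Pareto front, and the
partial-dependence panel."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .campaign_io import ExperimentResult
from .analysis import campaign_convergence, campaign_front, campaign_points
from .hypervolume import point_hypervolume
from .pdp import PDPCurve

__all__ = ["convergence_plot", "front_plot", "pdp_panel"]


def convergence_plot(results: Sequence[ExperimentResult], objective: str,
                     path: str) -> None:
    """Hypervolume contributions per experiment and total per batch."""
    done = [r for r in results if not r.pending]
    pts = campaign_points(done, objective)
    series = campaign_convergence(done, objective)
    batches = sorted({r.batch for r in done})
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(1, len(done) + 1)
    ax.scatter(x, [point_hypervolume(p) for p in pts], s=18, c="tab:orange",
               label="HV contribution")
    # total HV drawn at each batch boundary
    ends = np.cumsum([sum(1 for r in done if r.batch == b) for b in batches])
    ax.step(ends, series, where="post", color="tab:blue", label="total HV")
    ax.set_xlabel("experiment")
    ax.set_ylabel("hypervolume (%)")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False)
    ax.set_title(f"yield / {objective}-selectivity campaign")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def front_plot(results: Sequence[ExperimentResult], objective: str,
               path: str) -> None:
    fr = campaign_front(results, objective)
    fig, ax = plt.subplots(figsize=(5, 5))
    ys = [p.yield_pct for p in fr.points]
    ss = [p.selectivity_pct for p in fr.points]
    ax.scatter(ys, ss, s=20, c="0.6")
    front = fr.front
    ax.plot([p.yield_pct for p in front], [p.selectivity_pct for p in front],
            "o-", c="tab:red", label="Pareto front")
    ax.set_xlabel("yield (%)")
    ax.set_ylabel(f"{objective}-selectivity (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pdp_panel(curves: Sequence[PDPCurve], path: str) -> None:
    """Objectives x parameters grid of partial-dependence curves."""
    objectives = sorted({c.objective for c in curves})
    params = list(dict.fromkeys(c.parameter for c in curves))
    fig, axes = plt.subplots(len(objectives), len(params),
                             figsize=(2.2 * len(params), 2.2 * len(objectives)),
                             squeeze=False, sharey="row")
    for i, obj in enumerate(objectives):
        for j, par in enumerate(params):
            ax = axes[i][j]
            cur = next(c for c in curves if c.objective == obj and c.parameter == par)
            ax.plot(cur.grid, cur.response, "-o", ms=2.5)
            if i == len(objectives) - 1:
                ax.set_xlabel(par, fontsize=7)
            if j == 0:
                ax.set_ylabel(obj.replace("_", "\n"), fontsize=7)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
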