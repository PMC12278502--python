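"""Pareto fronts and 2-D hypervolume analytics for campaign evaluation.

Both objectives live on a percentage scale, so the objective plane is the
100 x 100 square with the reference point at the origin: a hypervolume of
100% corresponds to 100% yield at 100% stereoselectivity. A single
experiment's "hypervolume contribution" is the area of its dominated
rectangle, yield x selectivity / 100; the total hypervolume of a point set
is the exact area of the union of those rectangles (2-D descending sweep),
again as a percentage of the full square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ObjectivePoint",
    "FrontResult",
    "point_hypervolume",
    "total_hypervolume",
    "total_hypervolume_xy",
    "pareto_front",
    "exclusive_contribution",
    "hv_convergence",
    "round_half_away",
]


@dataclass(frozen=True)
class ObjectivePoint:
    """A (yield %, selectivity %) pair in the maximization plane.

    Yields slightly above 100% occur (NMR integration error) and are kept
    as-is; selectivity is a fraction of product and must lie in [0, 100].
    """

    yield_pct: float
    selectivity_pct: float

    def __post_init__(self):
        if self.yield_pct < 0:
            raise ValueError(f"yield must be >= 0, got {self.yield_pct}")
        if not 0 <= self.selectivity_pct <= 100:
            raise ValueError(
                f"selectivity must be in [0, 100], got {self.selectivity_pct}"
            )


@dataclass(frozen=True)
class FrontResult:
    points: tuple
    is_front: tuple  # parallel bool flags
    total_hv: float

    @property
    def front(self) -> tuple:
        """Front members sorted by ascending yield."""
        members = [p for p, f in zip(self.points, self.is_front) if f]
        return tuple(sorted(members, key=lambda p: (p.yield_pct, p.selectivity_pct)))


def _as_array(points: Iterable[ObjectivePoint]) -> np.ndarray:
    return np.array(
        [(p.yield_pct, p.selectivity_pct) for p in points], dtype=float
    ).reshape(-1, 2)


def point_hypervolume(p: ObjectivePoint) -> float:
    """Rectangle area from the origin, as % of the 100 x 100 square."""
    return p.yield_pct * p.selectivity_pct / 100.0


def total_hypervolume_xy(yields: Sequence[float], sels: Sequence[float]) -> float:
    """Union area over raw coordinate arrays (no ObjectivePoint validation).

    Negative coordinates are clipped to 0 (they dominate nothing).
    """
    y = np.clip(np.asarray(yields, dtype=float), 0.0, None)
    s = np.clip(np.asarray(sels, dtype=float), 0.0, None)
    if y.size == 0:
        return 0.0
    order = np.argsort(-y, kind="stable")
    area = 0.0
    best_sel = 0.0
    for i in order:
        if s[i] > best_sel:
            area += y[i] * (s[i] - best_sel)
            best_sel = s[i]
    return area / 100.0


def total_hypervolume(points: Sequence[ObjectivePoint]) -> float:
    """Exact union area of the dominated rectangles (reference (0, 0)).

    Descending sweep over yield: each point contributes a strip of width
    ``yield`` for whatever selectivity range no wider point has covered.
    Empty input returns 0 by convention.
    """
    pts = _as_array(points)
    if pts.size == 0:
        return 0.0
    return total_hypervolume_xy(pts[:, 0], pts[:, 1])


def pareto_front(points: Sequence[ObjectivePoint]) -> FrontResult:
    """Flag the non-dominated points (maximizing both axes).

    Weak dominance removes duplicates: of coincident points one
    representative (the first) stays on the front.
    """
    pts = _as_array(points)
    n = len(pts)
    flags = np.zeros(n, dtype=bool)
    if n:
        # sort by yield desc, then selectivity desc; stable keeps first-seen
        order = np.lexsort((-pts[:, 1], -pts[:, 0]))
        best_sel = -np.inf
        seen: set[tuple[float, float]] = set()
        for i in order:
            y, s = pts[i]
            if s > best_sel and (y, s) not in seen:
                flags[i] = True
                seen.add((y, s))
                best_sel = s
    return FrontResult(tuple(points), tuple(bool(f) for f in flags),
                       total_hypervolume(points))


def exclusive_contribution(points: Sequence[ObjectivePoint], i: int) -> float:
    """Marginal hypervolume lost when point ``i`` is removed.

    This is the exclusive (joint) contribution used in convergence-style
    analyses; the per-experiment column printed alongside campaign tables
    is the plain rectangle area (:func:`point_hypervolume`) instead.
    """
    others = [p for j, p in enumerate(points) if j != i]
    return total_hypervolume(points) - total_hypervolume(others)


def hv_convergence(points: Sequence[ObjectivePoint],
                   batches: Sequence[int]) -> list[float]:
    """Cumulative total hypervolume after each batch.

    ``batches`` carries one label per point; the series has one entry per
    distinct batch label (ascending) and is monotone non-decreasing.
    """
    if len(points) != len(batches):
        raise ValueError("one batch label per point required")
    if any(b is None for b in batches):
        raise ValueError("missing batch labels")
    labels = sorted(set(batches))
    series = []
    acc: list[ObjectivePoint] = []
    for lab in labels:
        acc.extend(p for p, b in zip(points, batches) if b == lab)
        series.append(total_hypervolume(acc))
    return series


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (the tables' convention)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0
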