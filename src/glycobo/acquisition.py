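"""Human-in-the-loop batch acquisition.

A campaign starts with a batch of 10 random experiments. Every later
batch holds 5 proposals, each independently flagged for exploration with
probability 0.25: exploration points come from Steinerberger-style
repulsive-energy sampling (space filling), exploitation points from the
model-estimated Pareto front of a random candidate pool, tie-broken by
predicted hypervolume gain over the observed front.

The loop is deliberately tolerant of human deviation: ``tell`` accepts
whatever conditions the experiments were actually run under, which need
not match the proposals.

A dual campaign runs a yield/β-selectivity and a yield/α-selectivity
optimizer side by side: each batch takes 2 proposals from the former and
3 from the latter (both purely exploitative by default), and all 5
results are fed back to both optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .campaign_io import ExperimentResult
from .hypervolume import total_hypervolume_xy
from .space import Conditions, ReactionSpace, encode, sample_random, validate_conditions
from .surrogate import (
    ALPHA_SELECTIVITY,
    BETA_SELECTIVITY,
    YIELD,
    ObjectiveSpec,
    SurrogateModel,
    fit_surrogate,
    inverse_transform,
    objective_value,
)

__all__ = [
    "AcquisitionConfig",
    "CampaignState",
    "ask",
    "tell",
    "pareto_exploit",
    "steinerberger_sample",
    "dual_ask",
    "dual_tell",
]

MODE_RANDOM = "random"
MODE_EXPLOIT = "pareto_exploit"
MODE_EXPLORE = "steinerberger_explore"


@dataclass
class AcquisitionConfig:
    init_batch_size: int = 10
    batch_size: int = 5
    explore_prob: float = 0.25
    pool_size: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.explore_prob <= 1.0:
            raise ValueError("explore_prob must be in [0, 1]")


@dataclass
class CampaignState:
    """All observations, surrogate pair and RNG state for one objective pair."""

    space: ReactionSpace
    selectivity: ObjectiveSpec
    rng: np.random.Generator
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    observations: list = field(default_factory=list)
    batch_log: list = field(default_factory=list)  # (batch index, [modes])
    yield_model: SurrogateModel | None = None
    sel_model: SurrogateModel | None = None
    _stale: bool = True

    @classmethod
    def new(cls, space: ReactionSpace, selectivity: str = "beta_selectivity",
            seed: int = 0, config: AcquisitionConfig | None = None) -> "CampaignState":
        spec = {"beta_selectivity": BETA_SELECTIVITY,
                "alpha_selectivity": ALPHA_SELECTIVITY}[selectivity]
        return cls(space=space, selectivity=spec,
                   rng=np.random.default_rng(seed),
                   config=config or AcquisitionConfig())

    # -- observed objective values ------------------------------------
    def objective_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(yield %, selectivity %) arrays over completed observations."""
        done = [r for r in self.observations if not r.pending]
        ys = np.array([r.yield_pct for r in done], dtype=float)
        ss = np.array([objective_value(self.selectivity, r.yield_pct, r.beta_pct)
                       for r in done], dtype=float)
        return ys, ss

    def ensure_models(self) -> None:
        """Refit both surrogates if observations changed since the last fit."""
        done = [r for r in self.observations if not r.pending]
        if not self._stale or len(done) < 2:
            return
        seed = int(self.rng.integers(2**31))
        obs_y = [(r.conditions, r.yield_pct) for r in done]
        obs_s = [(r.conditions,
                  objective_value(self.selectivity, r.yield_pct, r.beta_pct))
                 for r in done]
        self.yield_model = fit_surrogate(obs_y, YIELD, self.space, seed=seed)
        self.sel_model = fit_surrogate(obs_s, self.selectivity, self.space,
                                       seed=seed + 1)
        self._stale = False


def _scaled(space: ReactionSpace, X: np.ndarray) -> np.ndarray:
    """Scale encoded vectors so every axis spans [0, 1] (for distances)."""
    lo = np.array([space.axis_range(p)[0] for p in space.parameters])
    hi = np.array([space.axis_range(p)[1] for p in space.parameters])
    return (np.atleast_2d(X) - lo) / (hi - lo)


def steinerberger_sample(existing: np.ndarray, space: ReactionSpace,
                         rng: np.random.Generator,
                         pool_size: int = 2000) -> Conditions:
    """Pick the pool candidate minimizing a repulsive energy against
    ``existing`` encoded points.

    The energy is the Steinerberger-type sum ``E(x) = sum_i -log ||x - x_i||``
    over the [0, 1]-scaled encoded cube, so far-from-everything candidates
    are preferred. With no existing points this reduces to one uniform
    random draw.
    """
    existing = np.asarray(existing, dtype=float).reshape(-1, len(space.parameters)) \
        if np.size(existing) else np.empty((0, len(space.parameters)))
    if existing.shape[0] == 0:
        return sample_random(space, 1, rng)[0]
    pool = sample_random(space, pool_size, rng)
    P = _scaled(space, np.array([encode(space, c) for c in pool]))
    E = _scaled(space, existing)
    d = np.linalg.norm(P[:, None, :] - E[None, :, :], axis=2)
    energy = -np.log(np.clip(d, 1e-9, None)).sum(axis=1)
    return pool[int(np.argmin(energy))]


def _pareto_mask(ys: np.ndarray, ss: np.ndarray) -> np.ndarray:
    """Non-dominated mask (maximize both), weak dominance keeps one copy."""
    n = len(ys)
    mask = np.zeros(n, dtype=bool)
    order = np.lexsort((-ss, -ys))
    best = -np.inf
    seen = set()
    for i in order:
        key = (ys[i], ss[i])
        if ss[i] > best and key not in seen:
            mask[i] = True
            seen.add(key)
            best = ss[i]
    return mask


def pareto_exploit(state: CampaignState, pool_size: int | None = None,
                   rng: np.random.Generator | None = None) -> Conditions:
    """One exploitation proposal from the model-estimated Pareto front.

    Draws a random candidate pool, predicts both objective means, keeps
    the predicted non-dominated subset, and returns the member with the
    largest predicted total-hypervolume gain over the observed front
    (ties broken randomly).
    """
    rng = rng if rng is not None else state.rng
    pool_size = pool_size or state.config.pool_size
    state.ensure_models()
    if state.yield_model is None:
        raise ValueError("need at least 2 observations before exploitation")
    pool = sample_random(state.space, pool_size, rng)
    X = np.array([encode(state.space, c) for c in pool])
    pred_y = inverse_transform(state.yield_model.predict_encoded(X))
    pred_s = inverse_transform(state.sel_model.predict_encoded(X))
    mask = _pareto_mask(pred_y, pred_s)
    idx = np.nonzero(mask)[0]
    obs_y, obs_s = state.objective_values()
    base = total_hypervolume_xy(obs_y, obs_s)
    gains = np.array([
        total_hypervolume_xy(np.append(obs_y, pred_y[i]),
                             np.append(obs_s, pred_s[i])) - base
        for i in idx
    ])
    best = idx[gains >= gains.max() - 1e-12]
    return pool[int(rng.choice(best))]


def ask(state: CampaignState) -> list[Conditions]:
    """Propose the next batch.

    With no observations: ``init_batch_size`` random conditions. Otherwise
    ``batch_size`` proposals, each independently exploration
    (Steinerberger) with probability ``explore_prob``, else exploitation
    (estimated Pareto front). Modes are recorded in the batch log.
    """
    batch_index = len(state.batch_log) + 1
    if not state.observations:
        props = sample_random(state.space, state.config.init_batch_size, state.rng)
        state.batch_log.append((batch_index, [MODE_RANDOM] * len(props)))
        return props
    state.ensure_models()
    props: list[Conditions] = []
    modes: list[str] = []
    existing = [encode(state.space, r.conditions) for r in state.observations
                if not r.pending]
    for _ in range(state.config.batch_size):
        explore = state.rng.random() < state.config.explore_prob
        if explore or state.yield_model is None:
            c = steinerberger_sample(
                np.array(existing + [encode(state.space, p) for p in props]),
                state.space, state.rng, state.config.pool_size)
            modes.append(MODE_EXPLORE)
        else:
            c = pareto_exploit(state)
            modes.append(MODE_EXPLOIT)
        props.append(c)
    state.batch_log.append((batch_index, modes))
    return props


def tell(state: CampaignState, results: list[ExperimentResult]) -> CampaignState:
    """Record executed experiments.

    Conditions may deviate from the proposals (human-in-the-loop);
    invalid conditions are rejected with their violations named, and
    results missing an objective value are rejected.
    """
    for r in results:
        violations = validate_conditions(state.space, r.conditions)
        if violations:
            raise ValueError("invalid conditions in tell: " + "; ".join(violations))
        if r.pending:
            raise ValueError("result is missing yield/ratio measurements")
    state.observations.extend(results)
    if results:
        state._stale = True
    return state


def dual_ask(state_beta: CampaignState, state_alpha: CampaignState,
             n_beta: int = 2, n_alpha: int = 3) -> tuple[list[Conditions], list[str]]:
    """One dual-campaign batch: ``n_beta`` exploitation proposals from the
    yield/β optimizer followed by ``n_alpha`` from the yield/α optimizer.

    Both optimizers run purely exploitative here (Pareto-front sampling);
    the returned provenance list marks each proposal "beta" or "alpha".
    """
    if state_beta.space is not state_alpha.space and \
            state_beta.space != state_alpha.space:
        raise ValueError("dual campaign requires both optimizers to share a space")
    props = [pareto_exploit(state_beta) for _ in range(n_beta)]
    props += [pareto_exploit(state_alpha) for _ in range(n_alpha)]
    provenance = ["beta"] * n_beta + ["alpha"] * n_alpha
    for st, n in ((state_beta, n_beta), (state_alpha, n_alpha)):
        st.batch_log.append((len(st.batch_log) + 1, [MODE_EXPLOIT] * (n_beta + n_alpha)))
    return props, provenance


def dual_tell(state_beta: CampaignState, state_alpha: CampaignState,
              results: list[ExperimentResult]) -> None:
    """Broadcast all batch results to both optimizers."""
    tell(state_beta, results)
    tell(state_alpha, results)
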