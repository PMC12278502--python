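"""A synthetic glycosylation-outcome oracle for closed-loop testing.

Wet-lab campaigns cannot be replayed, so this module provides a
deterministic response surface over the reaction space that encodes the
qualitative structure the campaigns uncovered:

* salt-directed stereoselectivity — LiI is always α-selective; LiBF4 and
  LiNTf2 are always β-selective; LiPF6 flips with sieve presence and
  solvent composition (β with sieves or MeCN-rich solvent, α without
  sieves in ether-rich solvent);
* low-to-moderate yields without an acid catalyst, and higher yields the
  stronger the acid;
* an essentially unreactive LiB(C6F5)4 system;
* additive Gaussian observation noise on both objectives.

Latent trend terms are logistic-squashed into valid percentage ranges.
The scenario is synthetic: it reproduces trends, not chemistry, and
passing closed-loop tests on it says nothing about real predictivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, CampaignState, ask, tell
from .campaign_io import ExperimentResult
from .hypervolume import hv_convergence, ObjectivePoint, total_hypervolume_xy
from .space import Conditions, ReactionSpace, build_default_space, is_valid, \
    sample_random, validate_conditions, SIEVE_CODES
from .surrogate import objective_value

__all__ = ["LabScenario", "default_scenario", "simulate_reaction",
           "run_campaign", "benchmark_optimizer"]


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class LabScenario:
    """Trend weights and noise level of the synthetic oracle."""

    # selectivity latent (β% = 100 * sigmoid(z))
    salt_beta_base: dict = field(default_factory=lambda: {
        "LiI": -2.8, "LiBF4": 1.5, "LiNTf2": 1.6,
        "LiClO4": 0.2, "LiOTf": 0.3, "LiB(C6F5)4": 0.0,
    })
    pf6_beta_branch: float = 1.1     # sieves present or MeCN-rich
    pf6_alpha_branch: float = -1.6   # no sieves, ether-rich
    pf6_neutral: float = 0.0
    pf6_mecn_rich: float = 0.35      # MeCN fraction above which PF6 turns β
    et2o_beta_slope: float = -0.6    # ether effect pushes α
    mecn_beta_slope: float = 0.25    # weak nitrile effect pushes β
    donor_sel_effect: float = 0.1    # β-configured donor nudges β product
    cold_beta_bonus: float = 0.1     # slight β increase at 0 °C
    sieve_sel_slope: float = 0.05    # per sieve-size code

    # yield latent (yield% = 105 * sigmoid(z))
    yield_base: float = 0.75
    acid_yield: dict = field(default_factory=lambda: {
        "None": -1.2, "Acetic": 0.3, "Formic": 0.55, "Oxalic": 0.8, "TFA": 1.0,
    })
    salt_yield: dict = field(default_factory=lambda: {
        "LiB(C6F5)4": -3.0, "LiI": 0.1,
    })
    acceptor_yield_slope: float = 0.25
    conc_yield_slope: float = 0.1
    sieve_yield_bonus: float = 0.15
    warm_yield_bonus: float = 0.1

    noise_sd: float = 5.0  # % on both objectives


def default_scenario(noise_sd: float = 5.0) -> LabScenario:
    return LabScenario(noise_sd=noise_sd)


def scenario_to_json(s: LabScenario) -> str:
    import dataclasses
    import json
    return json.dumps(dataclasses.asdict(s), indent=2)


def scenario_from_json(text: str) -> LabScenario:
    import json
    return LabScenario(**json.loads(text))


def _noiseless(scenario: LabScenario, c: Conditions) -> tuple[float, float]:
    s = scenario
    if c.li_salt == "LiPF6":
        if c.sieves != "None" or c.part_mecn > s.pf6_mecn_rich:
            z = s.pf6_beta_branch
        elif c.part_et2o > c.part_mecn:
            z = s.pf6_alpha_branch
        else:
            z = s.pf6_neutral
    else:
        z = s.salt_beta_base[c.li_salt]
    z += s.et2o_beta_slope * c.part_et2o
    z += s.mecn_beta_slope * c.part_mecn
    z += s.donor_sel_effect * (1 if c.donor_config == "beta" else -1)
    z += s.cold_beta_bonus * (1 if c.temp == 0 else 0)
    z += s.sieve_sel_slope * SIEVE_CODES[c.sieves]
    beta = 100.0 * _sigmoid(z)

    zy = s.yield_base + s.acid_yield[c.acid] + s.salt_yield.get(c.li_salt, 0.0)
    zy += s.acceptor_yield_slope * (c.acceptor_eq - 1.9) / 1.1
    zy += s.conc_yield_slope * (c.conc - 0.17) / 0.14
    zy += s.sieve_yield_bonus * (1 if c.sieves != "None" else 0)
    zy += s.warm_yield_bonus * (1 if c.temp == 25 else 0)
    yld = 105.0 * _sigmoid(zy)
    return float(np.clip(yld, 0.0, 105.0)), float(np.clip(beta, 0.0, 100.0))


def simulate_reaction(scenario: LabScenario, c: Conditions,
                      rng: np.random.Generator | None = None,
                      space: ReactionSpace | None = None) -> ExperimentResult:
    """Measured outcome for one set of conditions.

    Deterministic given the scenario and conditions when ``noise_sd`` is 0
    (or rng is None); otherwise adds Gaussian noise and clips to the
    measurable ranges (yield may exceed 100, as real NMR yields do).
    """
    space = space or build_default_space()
    violations = validate_conditions(space, c)
    if violations:
        raise ValueError("invalid conditions: " + "; ".join(violations))
    yld, beta = _noiseless(scenario, c)
    if scenario.noise_sd > 0 and rng is not None:
        yld = float(np.clip(yld + rng.normal(0.0, scenario.noise_sd), 0.0, 110.0))
        beta = float(np.clip(beta + rng.normal(0.0, scenario.noise_sd), 0.0, 100.0))
    return ExperimentResult(conditions=c, yield_pct=yld, beta_pct=beta)


def run_campaign(scenario: LabScenario, strategy: str = "glyco-bo",
                 budget: int = 55, seed: int = 0,
                 selectivity: str = "beta_selectivity",
                 config: AcquisitionConfig | None = None,
                 space: ReactionSpace | None = None) -> pd.DataFrame:
    """One closed ask/simulate/tell loop on the virtual lab.

    ``strategy`` is ``glyco-bo`` (the full acquisition loop) or
    ``random`` (uniform sampling in the same batch structure). Returns a
    tidy frame with one row per batch: cumulative total hypervolume of
    the observed objective points after that batch.
    """
    if strategy not in ("glyco-bo", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    space = space or build_default_space()
    config = config or AcquisitionConfig()
    state = CampaignState.new(space, selectivity=selectivity, seed=seed,
                              config=config)
    noise_rng = np.random.default_rng((seed + 987654321) % 2**31)
    batch = 0
    while len(state.observations) < budget:
        batch += 1
        if strategy == "glyco-bo":
            props = ask(state)
        else:
            n = config.init_batch_size if not state.observations else config.batch_size
            props = sample_random(space, n, state.rng)
            state.batch_log.append((batch, ["random"] * n))
        props = props[: budget - len(state.observations)]
        results = []
        for c in props:
            r = simulate_reaction(scenario, c, noise_rng, space)
            r.batch = batch
            results.append(r)
        tell(state, results)
    ys, ss = state.objective_values()
    batches = [r.batch for r in state.observations]
    labels = sorted(set(batches))
    series = []
    for lab in labels:
        upto = [i for i, b in enumerate(batches) if b <= lab]
        series.append(total_hypervolume_xy(ys[upto], ss[upto]))
    return pd.DataFrame({
        "strategy": strategy, "seed": seed, "batch": labels, "cum_hv": series,
    })


def benchmark_optimizer(scenario: LabScenario, budget: int = 55,
                        replicates: int = 20, seed: int = 0,
                        selectivity: str = "beta_selectivity",
                        config: AcquisitionConfig | None = None,
                        strategies: tuple = ("glyco-bo", "random")) -> pd.DataFrame:
    """Paired benchmark of the acquisition loop against random sampling.

    Each replicate runs every strategy from its own seed (derived from
    ``seed``) on the same scenario. Returns the concatenated per-batch
    convergence frames; the final row per (strategy, seed) is the final
    total hypervolume.
    """
    if budget < (config or AcquisitionConfig()).init_batch_size:
        raise ValueError("budget must cover the initiation batch")
    seeds = np.random.default_rng(seed).integers(2**31, size=replicates)
    frames = []
    for rep_seed in seeds:
        for strat in strategies:
            frames.append(run_campaign(scenario, strat, budget, int(rep_seed),
                                       selectivity, config))
    return pd.concat(frames, ignore_index=True)
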