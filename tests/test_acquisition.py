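import numpy as np
import pytest
from scipy import stats

from glycobo import (
    AcquisitionConfig,
    CampaignState,
    ExperimentResult,
    ask,
    dual_ask,
    dual_tell,
    pareto_exploit,
    steinerberger_sample,
    tell,
    validate_conditions,
)
from glycobo.acquisition import MODE_EXPLOIT, MODE_EXPLORE, MODE_RANDOM
from glycobo.space import build_default_space, encode, sample_random
from glycobo.virtual_lab import default_scenario, simulate_reaction

FAST = AcquisitionConfig(pool_size=150)


def seeded_state(space, seed=0, n_obs=10, config=None, selectivity="beta_selectivity"):
    """A state initialized with noiseless virtual-lab observations."""
    state = CampaignState.new(space, selectivity=selectivity, seed=seed,
                              config=config or FAST)
    scen = default_scenario(noise_sd=0.0)
    conds = sample_random(space, n_obs, np.random.default_rng(seed + 1))
    results = [simulate_reaction(scen, c, space=space) for c in conds]
    if results:
        tell(state, results)
    return state


def fixture_state(space, campaign, seed=0, selectivity="beta_selectivity"):
    state = CampaignState.new(space, selectivity=selectivity, seed=seed, config=FAST)
    tell(state, list(campaign))
    return state


class TestAsk:
    def test_fresh_state_gets_ten_random_proposals(self, space):
        state = CampaignState.new(space, seed=0, config=FAST)
        props = ask(state)
        assert len(props) == 10
        assert state.batch_log == [(1, [MODE_RANDOM] * 10)]
        for c in props:
            assert validate_conditions(space, c) == []

    def test_zero_exploration_probability_is_pure_exploitation(self, space):
        cfg = AcquisitionConfig(pool_size=150, explore_prob=0.0)
        state = seeded_state(space, config=cfg)
        ask(state)
        assert state.batch_log[-1][1] == [MODE_EXPLOIT] * 5

    def test_exploration_fraction_matches_bernoulli_rate(self, space):
        # 200 seeded batches of 5 at 25% exploration
        state = seeded_state(space, seed=7, config=AcquisitionConfig(pool_size=60))
        modes = []
        for _ in range(200):
            props = ask(state)
            modes += state.batch_log[-1][1]
            for c in props:
                assert validate_conditions(space, c) == []
        n = len(modes)
        frac = modes.count(MODE_EXPLORE) / n
        lo, hi = stats.binom.interval(0.99, n, 0.25)
        assert lo / n <= frac <= hi / n

    def test_seeded_determinism(self, space):
        a = ask(seeded_state(space, seed=4))
        b = ask(seeded_state(space, seed=4))
        assert a == b


class TestTell:
    def test_human_deviation_from_proposal_accepted(self, space):
        state = seeded_state(space, n_obs=0)
        props = ask(state)
        deviated = props[0].with_value("li_salt_eq", 3.33).with_value("conc", 0.11)
        r = ExperimentResult(conditions=deviated, yield_pct=50, beta_pct=50)
        tell(state, [r])
        assert state.observations[-1].conditions.li_salt_eq == 3.33

    def test_empty_tell_changes_nothing(self, space):
        state = seeded_state(space)
        n = len(state.observations)
        tell(state, [])
        assert len(state.observations) == n

    def test_duplicate_batches_are_both_recorded(self, space):
        state = seeded_state(space, n_obs=0)
        scen = default_scenario(noise_sd=0.0)
        results = [simulate_reaction(scen, c, space=space)
                   for c in sample_random(space, 5, np.random.default_rng(0))]
        tell(state, results)
        tell(state, results)
        assert len(state.observations) == 10

    def test_invalid_conditions_rejected_with_violations(self, space):
        state = seeded_state(space)
        bad = state.observations[0].conditions.with_value("part_et2o", 0.8) \
                                              .with_value("part_mecn", 0.8)
        with pytest.raises(ValueError, match="part_et2o"):
            tell(state, [ExperimentResult(conditions=bad, yield_pct=1, beta_pct=1)])

    def test_pending_results_rejected(self, space):
        state = seeded_state(space)
        c = state.observations[0].conditions
        with pytest.raises(ValueError, match="missing"):
            tell(state, [ExperimentResult(conditions=c)])


class TestSteinerberger:
    def test_empty_existing_gives_valid_random_point(self, space, rng):
        c = steinerberger_sample(np.empty((0, space.dim)), space, rng, pool_size=50)
        assert validate_conditions(space, c) == []

    def test_repulsion_from_cube_center(self, space):
        # returned point should be farther from a central existing point
        # than the pool median, across seeded repeats
        lo = np.array([space.axis_range(p)[0] for p in space.parameters])
        hi = np.array([space.axis_range(p)[1] for p in space.parameters])
        center = (lo + hi) / 2
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            c = steinerberger_sample(center[None, :], space, r, pool_size=100)
            r2 = np.random.default_rng(seed)
            pool = sample_random(space, 100, r2)
            scale = hi - lo
            d = lambda x: np.linalg.norm((encode(space, x) - center) / scale)
            med = np.median([d(p) for p in pool])
            wins += d(c) > med
        assert wins == 100

    def test_point_between_two_occupied_corners_avoids_both(self, space):
        # the -log kernel maximizes the product of distances, so the
        # returned point's min distance to the occupied corners beats the
        # pool median (the exact maximin point would need a steeper kernel)
        lo = np.array([space.axis_range(p)[0] for p in space.parameters])
        hi = np.array([space.axis_range(p)[1] for p in space.parameters])
        existing = np.vstack([lo, hi])
        scale = hi - lo
        for seed in range(50):
            r = np.random.default_rng(seed)
            c = steinerberger_sample(existing, space, r, pool_size=100)
            pool = sample_random(space, 100, np.random.default_rng(seed))

            def mind(x):
                e = encode(space, x)
                return min(np.linalg.norm((e - lo) / scale),
                           np.linalg.norm((e - hi) / scale))

            assert mind(c) > np.median([mind(p) for p in pool])

    def test_returned_candidate_attains_pool_minimum_energy(self, space):
        lo = np.array([space.axis_range(p)[0] for p in space.parameters])
        hi = np.array([space.axis_range(p)[1] for p in space.parameters])
        existing = np.vstack([lo, (lo + hi) / 2])
        c = steinerberger_sample(existing, space, np.random.default_rng(9),
                                 pool_size=120)
        pool = sample_random(space, 120, np.random.default_rng(9))
        scale = hi - lo

        def energy(x):
            e = (encode(space, x) - lo) / scale
            d = np.linalg.norm(e - (existing - lo) / scale, axis=1)
            return -np.log(np.clip(d, 1e-9, None)).sum()

        assert energy(c) == pytest.approx(min(energy(p) for p in pool))


class TestParetoExploit:
    def test_constant_surrogates_still_return_valid_conditions(self, space):
        state = seeded_state(space, n_obs=0)
        conds = sample_random(space, 5, np.random.default_rng(2))
        tell(state, [ExperimentResult(conditions=c, yield_pct=50.0, beta_pct=50.0)
                     for c in conds])
        c = pareto_exploit(state, pool_size=100)
        assert validate_conditions(space, c) == []

    def test_exploitation_points_on_fixture_campaign(self, space, campaign1):
        state = fixture_state(space, campaign1, seed=3)
        train = {r.conditions for r in campaign1}
        for _ in range(20):
            c = pareto_exploit(state, pool_size=150)
            assert validate_conditions(space, c) == []
            assert c not in train

    def test_requires_observations(self, space):
        state = CampaignState.new(space, seed=0, config=FAST)
        with pytest.raises(ValueError, match="observations"):
            pareto_exploit(state)


class TestDualCampaign:
    def test_two_beta_three_alpha_provenance(self, space, campaign1):
        sb = fixture_state(space, campaign1, seed=1, selectivity="beta_selectivity")
        sa = fixture_state(space, campaign1, seed=2, selectivity="alpha_selectivity")
        props, prov = dual_ask(sb, sa)
        assert prov == ["beta", "beta", "alpha", "alpha", "alpha"]
        assert len(props) == 5
        for c in props:
            assert validate_conditions(space, c) == []

    def test_dual_tell_broadcasts_to_both(self, space, campaign1):
        sb = fixture_state(space, campaign1, seed=1)
        sa = fixture_state(space, campaign1, seed=2, selectivity="alpha_selectivity")
        scen = default_scenario(noise_sd=0.0)
        results = [simulate_reaction(scen, c, space=space)
                   for c in sample_random(space, 5, np.random.default_rng(5))]
        nb, na = len(sb.observations), len(sa.observations)
        dual_tell(sb, sa, results)
        assert len(sb.observations) == nb + 5
        assert len(sa.observations) == na + 5

    def test_zero_sized_dual_batch_is_empty(self, space, campaign1):
        sb = fixture_state(space, campaign1, seed=1)
        sa = fixture_state(space, campaign1, seed=2, selectivity="alpha_selectivity")
        props, prov = dual_ask(sb, sa, n_beta=0, n_alpha=0)
        assert props == [] and prov == []

    def test_space_mismatch_rejected(self, space, campaign1):
        other = build_default_space({**{s: i + 1 for i, s in enumerate(
            ["LiBF4", "LiI", "LiClO4", "LiOTf", "LiNTf2", "LiPF6", "LiB(C6F5)4"])}})
        sb = fixture_state(space, campaign1, seed=1)
        sa = CampaignState.new(other, selectivity="alpha_selectivity", seed=2)
        with pytest.raises(ValueError, match="space"):
            dual_ask(sb, sa)
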