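import numpy as np
import pytest

import lipidsim as L
from lipidsim.config import ConfigurationError, ReactionParameters, default_config
from lipidsim.engine import (
    apply_reaction_once,
    draw_executions,
    draw_executions_loop,
    reaction_probability,
    substrate_saturation,
)
from lipidsim.lipids import C16_0, C18_1, CHAIN_INDEX, LipidClass
from lipidsim.network import AcetylCoASynthase, ErgosterolSynthase, PSSynthase

from conftest import make_empty_state


class TestSubstrateSaturation:
    def test_empty_pool_gives_zero(self):
        assert substrate_saturation(0, 17.0) == 0.0

    def test_half_saturation_at_km(self):
        assert substrate_saturation(42.0, 42.0) == pytest.approx(0.5)

    def test_three_km_gives_three_quarters(self):
        assert substrate_saturation(3 * 11.0, 11.0) == pytest.approx(0.75)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            substrate_saturation(-1.0, 10.0)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            substrate_saturation(1.0, 0.0)

    def test_monotone_and_below_one(self):
        km = 7.0
        values = [substrate_saturation(c, km) for c in np.linspace(0, 1e6, 50)]
        assert all(0.0 <= v < 1.0 for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestReactionProbability:
    def test_single_substrate_at_km(self, empty_state):
        r = AcetylCoASynthase("acetyl_coa_synthase",
                              ReactionParameters(n_max=10, km={"pyruvate": 50.0}))
        empty_state.pools.counts["pyruvate"] = 50.0
        assert reaction_probability(r, empty_state) == pytest.approx(0.5)

    def test_two_substrates_product(self, empty_state):
        r = PSSynthase("ps_synthase",
                       ReactionParameters(n_max=5, km={"CDP_DG": 10.0, "serine": 20.0}))
        empty_state.pools.counts["serine"] = 20.0
        idx = CHAIN_INDEX[LipidClass.CDP_DG][(C16_0, C18_1)]
        empty_state.free_lipids[LipidClass.CDP_DG][idx] = 10
        assert reaction_probability(r, empty_state) == pytest.approx(0.25)

    def test_any_empty_substrate_absorbs(self, empty_state):
        r = PSSynthase("ps_synthase",
                       ReactionParameters(n_max=5, km={"CDP_DG": 10.0, "serine": 20.0}))
        empty_state.pools.counts["serine"] = 1000.0
        assert reaction_probability(r, empty_state) == 0.0

    def test_missing_km_is_a_load_time_error(self):
        with pytest.raises(ConfigurationError):
            PSSynthase("ps_synthase", ReactionParameters(n_max=5, km={"CDP_DG": 10.0}))


class TestDrawExecutions:
    def test_degenerate_cases(self, rng):
        assert draw_executions(650, 0.0, rng) == 0
        assert draw_executions(5, 1.0, rng) == 5
        assert draw_executions(0, 0.7, rng) == 0

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_executions(5, 1.5, rng)

    def test_binomial_matches_uniform_loop_oracle(self):
        """The binomial shortcut and the literal draw-n_max-uniforms protocol
        agree in mean and variance over 1e5 trials (n_max=650, p=0.5)."""
        n_max, p, trials = 650, 0.5, 100_000
        rng1 = np.random.default_rng(42)
        binom = np.array([draw_executions(n_max, p, rng1) for _ in range(trials)])

        rng2 = np.random.default_rng(43)
        loop = np.concatenate([
            np.count_nonzero(rng2.random((chunk, n_max)) < p, axis=1)
            for chunk in [5000] * (trials // 5000)
        ])
        se_mean = np.sqrt(n_max * p * (1 - p) / trials)
        assert abs(binom.mean() - n_max * p) < 4 * se_mean
        assert abs(loop.mean() - n_max * p) < 4 * se_mean
        assert abs(binom.mean() - loop.mean()) < 5 * se_mean
        # variances agree with each other and with n*p*(1-p) within a few %
        assert binom.var() == pytest.approx(n_max * p * (1 - p), rel=0.05)
        assert loop.var() == pytest.approx(n_max * p * (1 - p), rel=0.05)

    def test_loop_oracle_small_case(self, rng):
        """Spot check of the literal loop against expectation 650*0.5=325."""
        draws = [draw_executions_loop(650, 0.5, rng) for _ in range(2000)]
        se = np.sqrt(650 * 0.25 / len(draws))
        assert abs(np.mean(draws) - 325.0) < 4 * se


class TestApplyReactionOnce:
    def test_ps_synthase_transforms_one_object(self, empty_state, rng):
        """A random CDP-DG is consumed with one serine; the PS product keeps
        the chains and a CMP is released."""
        r = PSSynthase("ps_synthase",
                       ReactionParameters(n_max=5, km={"CDP_DG": 10.0, "serine": 20.0}))
        idx = CHAIN_INDEX[LipidClass.CDP_DG][(C16_0, C18_1)]
        empty_state.free_lipids[LipidClass.CDP_DG][idx] = 1
        empty_state.pools.counts["serine"] = 100.0
        assert apply_reaction_once(r, empty_state, rng)
        assert empty_state.free_lipids[LipidClass.CDP_DG][idx] == 0
        assert empty_state.free_lipids[LipidClass.PS][idx] == 1
        assert empty_state.pools.counts["serine"] == 99.0
        assert empty_state.byproducts["CMP"] == 1

    def test_empty_substrate_is_noop(self, empty_state, rng):
        r = PSSynthase("ps_synthase",
                       ReactionParameters(n_max=5, km={"CDP_DG": 10.0, "serine": 20.0}))
        empty_state.pools.counts["serine"] = 100.0
        assert not apply_reaction_once(r, empty_state, rng)
        assert empty_state.pools.counts["serine"] == 100.0

    def test_ergosterol_spends_18_acetyl_coa(self, empty_state, rng):
        r = ErgosterolSynthase("ergosterol_synthase",
                               ReactionParameters(n_max=4, km={"acetyl_coa": 10.0}))
        empty_state.pools.counts["acetyl_coa"] = 20.0
        assert apply_reaction_once(r, empty_state, rng)
        assert empty_state.pools.counts["acetyl_coa"] == 2.0
        assert empty_state.free_lipids[LipidClass.ES][0] == 1
        # a second execution no-ops: only 2 units remain
        assert not apply_reaction_once(r, empty_state, rng)


class TestStep:
    def test_fixed_seed_reproduces_state(self, cfg):
        cfg.horizon, cfg.g1_end, cfg.s_end, cfg.g2_end = 60.0, 30.0, 40.0, 50.0
        t1 = L.run(cfg, seed=5)
        t2 = L.run(cfg, seed=5)
        for name in t1.membrane_counts:
            assert np.array_equal(t1.membrane_counts[name], t2.membrane_counts[name])
        assert t1.final_state.pools.counts == t2.final_state.pools.counts
        for cls in LipidClass:
            assert np.array_equal(t1.final_state.free_lipids[cls],
                                  t2.final_state.free_lipids[cls])

    def test_empty_state_only_refills(self, cfg, empty_state):
        from lipidsim.engine import step
        from lipidsim.network import build_network
        empty_state.pools.refill_rates = {"pyruvate": 2.5}
        reactions = build_network(cfg)
        step(empty_state, reactions, cfg, empty_state.rng)
        assert empty_state.pools.counts["pyruvate"] == 2.5
        assert empty_state.total_membrane_lipids() == 0
        assert empty_state.t == cfg.dt

    def test_toy_reaction_mean_flux(self, rng):
        """1000 steps of a single rule at p=0.5, n_max=10: ~5000 executions."""
        r = AcetylCoASynthase("acetyl_coa_synthase",
                              ReactionParameters(n_max=10, km={"pyruvate": 1000.0}))
        state = make_empty_state(rng)
        total = 0
        for _ in range(1000):
            state.pools.counts["pyruvate"] = 1000.0  # held constant
            k = draw_executions(10, reaction_probability(r, state), rng)
            total += r.apply(state, k, rng)
        sd = np.sqrt(1000 * 10 * 0.25)
        assert abs(total - 5000) < 4 * sd

    def test_stochastic_mean_matches_deterministic_mm(self, rng):
        """With constant substrate S, mean executions over 1e4 steps match the
        deterministic Michaelis-Menten flux n_max*S/(Km+S) within 3 SE."""
        n_max, km, s_level, n_steps = 20, 100.0, 150.0, 10_000
        r = AcetylCoASynthase("acetyl_coa_synthase",
                              ReactionParameters(n_max=n_max, km={"pyruvate": km}))
        state = make_empty_state(rng)
        p = s_level / (km + s_level)
        total = 0
        for _ in range(n_steps):
            state.pools.counts["pyruvate"] = s_level
            total += r.apply(state, draw_executions(n_max, p, rng), rng)
        expected = n_max * p
        se = np.sqrt(n_max * p * (1 - p) / n_steps)
        assert abs(total / n_steps - expected) < 3 * se
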