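import numpy as np
import pytest

import lipidsim as L
from lipidsim.config import ReactionParameters, default_config
from lipidsim.lipids import (
    C16_0,
    C16_1,
    C18_0,
    C18_1,
    CHAIN_INDEX,
    CHAIN_SPACE,
    LipidClass,
    validate_chains,
)
from lipidsim.network import (
    FattyAcidSynthase,
    PASynthase,
    TAGLipase,
    TAGSynthase,
    build_network,
    species_graph,
)

from conftest import make_empty_state


def _reaches(graph, src, dst):
    seen, stack = set(), [src]
    while stack:
        node = stack.pop()
        if node == dst:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(graph.get(node, ()))
    return False


class TestTopology:
    def test_published_maxima_are_the_defaults(self):
        cfg = default_config()
        assert cfg.reactions["acetyl_coa_synthase"].n_max == 650
        assert cfg.reactions["pc_synthase"].n_max == 5

    @pytest.mark.parametrize("src,dst", [
        ("glycerol_3_p", "PA"), ("dhap", "PA"),
        ("PA", "PI"), ("PA", "CL"), ("PA", "PS"),
        ("PS", "PC"), ("pyruvate", "ES"), ("acetyl_coa", "SE"),
        ("PA", "TAG"), ("ceramide", "SL"), ("PI", "SL"),
        ("glucose_6_p", "PI"),
    ])
    def test_pathway_reachability(self, src, dst):
        assert _reaches(species_graph(), src, dst)

    def test_network_builds_all_configured_rules(self):
        cfg = default_config()
        reactions = build_network(cfg)
        assert len(reactions) == len(cfg.reactions)
        assert {r.name for r in reactions} == set(cfg.reactions)

    def test_unknown_reaction_name_rejected(self):
        cfg = default_config()
        cfg.reactions["frobnicase"] = ReactionParameters(n_max=1, km={})
        with pytest.raises(KeyError):
            build_network(cfg)


class TestFattyAcidSynthase:
    def test_species_frequencies_follow_weights(self, rng):
        weights = (0.09, 0.30, 0.11, 0.50)
        r = FattyAcidSynthase("fatty_acid_synthase", ReactionParameters(
            n_max=10, km={"acetyl_coa": 1.0}, fa_weights=weights))
        state = make_empty_state(rng)
        state.pools.counts["acetyl_coa"] = 1e7
        n = 10_000
        r.apply(state, n, rng)
        freqs = state.free_fatty_acids / n
        for w, f in zip(weights, freqs):
            sigma = np.sqrt(w * (1 - w) / n)
            assert abs(f - w) < 4 * sigma

    def test_acetyl_cost_per_chain(self, rng):
        """A C16 chain costs 8 acetyl-CoA units, a C18 chain 9."""
        for weights, cost in [((1.0, 0.0, 0.0, 0.0), 8), ((0.0, 0.0, 0.0, 1.0), 9)]:
            r = FattyAcidSynthase("fatty_acid_synthase", ReactionParameters(
                n_max=10, km={"acetyl_coa": 1.0}, fa_weights=weights))
            state = make_empty_state(rng)
            state.pools.counts["acetyl_coa"] = 100.0
            r.apply(state, 1, rng)
            assert state.pools.counts["acetyl_coa"] == 100.0 - cost

    def test_no_acetyl_coa_no_chains(self, rng):
        r = FattyAcidSynthase("fatty_acid_synthase", ReactionParameters(
            n_max=10, km={"acetyl_coa": 1.0}))
        state = make_empty_state(rng)
        assert r.apply(state, 10, rng) == 0
        assert state.free_fatty_acids.sum() == 0


class TestAcylation:
    def _pa_synthase(self):
        return PASynthase("pa_synthase", ReactionParameters(
            n_max=10, km={"lysoPA": 1.0, "unsaturated_fatty_acid": 1.0}))

    def test_sn2_draws_only_unsaturated(self, rng):
        state = make_empty_state(rng)
        state.free_lipids[LipidClass.LYSO_PA][0] = 50  # C16:0 at sn1
        state.free_fatty_acids[:] = (100, 30, 100, 20)  # mostly saturated
        self._pa_synthase().apply(state, 50, rng)
        pa = state.free_lipids[LipidClass.PA]
        assert pa.sum() == 50
        for idx in np.nonzero(pa)[0]:
            validate_chains(LipidClass.PA, CHAIN_SPACE[LipidClass.PA][idx])
        # all 50 sn2 chains came from the 50 unsaturated ones
        assert state.free_fatty_acids[1] + state.free_fatty_acids[3] == 0

    def test_without_unsaturated_chains_acylation_noops(self, rng):
        state = make_empty_state(rng)
        state.free_lipids[LipidClass.LYSO_PA][0] = 10
        state.free_fatty_acids[:] = (5, 0, 5, 0)  # saturated only
        assert self._pa_synthase().apply(state, 10, rng) == 0
        assert state.free_lipids[LipidClass.PA].sum() == 0


class TestHeadgroupEdits:
    def test_ps_pe_pc_roundtrip_preserves_chains(self, cfg, rng):
        """Head-group chemistry never touches the acyl chains."""
        reactions = {r.name: r for r in build_network(cfg)}
        state = make_empty_state(rng)
        state.pools.counts["serine"] = 1000.0
        start = rng.multinomial(200, np.full(8, 1 / 8)).astype(np.int64)
        state.free_lipids[LipidClass.CDP_DG] = start.copy()
        reactions["ps_synthase"].apply(state, 200, rng)
        reactions["ps_decarboxylase"].apply(state, 200, rng)
        reactions["pc_synthase"].apply(state, 200, rng)
        assert np.array_equal(state.free_lipids[LipidClass.PC], start)
        assert state.free_lipids[LipidClass.CDP_DG].sum() == 0

    def test_tag_synthase_lipase_roundtrip(self, rng):
        """Acylation to TAG followed by lipolysis restores the DAG/FA multisets."""
        synth = TAGSynthase("tag_synthase", ReactionParameters(
            n_max=10, km={"DAG": 1.0, "fatty_acid": 1.0}))
        lipase = TAGLipase("tag_lipase", ReactionParameters(n_max=10, km={"TAG": 1.0}))
        state = make_empty_state(rng)
        dag0 = rng.multinomial(60, np.full(8, 1 / 8)).astype(np.int64)
        fa0 = rng.multinomial(60, [0.25] * 4).astype(np.int64)
        state.free_lipids[LipidClass.DAG] = dag0.copy()
        state.free_fatty_acids = fa0.copy()
        synth.apply(state, 60, rng)
        assert state.free_lipids[LipidClass.TAG].sum() == 60
        lipase.apply(state, 60, rng)
        assert np.array_equal(state.free_lipids[LipidClass.DAG], dag0)
        assert np.array_equal(state.free_fatty_acids, fa0)
        assert state.free_lipids[LipidClass.TAG].sum() == 0


class TestCarbonLedger:
    def test_acetyl_consumption_accounts_for_every_chain_and_sterol(self, cfg):
        """Cumulative acetyl-CoA consumption equals 8*C16 + 9*C18 + 13*C26
        chains plus 18 per ergosterol, exactly."""
        cfg.horizon, cfg.g1_end, cfg.s_end, cfg.g2_end = 300.0, 150.0, 200.0, 250.0
        state = L.run(cfg, seed=3).final_state
        chains = state.produced_chains
        expected = (8 * (chains[0] + chains[1]) + 9 * (chains[2] + chains[3])
                    + 13 * chains[4] + 18 * state.produced_es)
        assert state.pools.consumed["acetyl_coa"] == expected
        assert expected > 0

    def test_ledger_is_nondecreasing(self, cfg):
        cfg.horizon, cfg.g1_end, cfg.s_end, cfg.g2_end = 100.0, 50.0, 70.0, 90.0
        traj = L.run(cfg, seed=9)
        assert np.all(np.diff(traj.acetyl_consumed) >= 0)
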