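"""The concrete yeast lipid network: ~19 lumped rules from central-carbon
precursors to membrane lipids.

The de novo pathway runs from pyruvate / triose phosphates to the membrane
lipid classes: acyl chains are built from acetyl-CoA (8 units per C16 chain,
9 per C18, 13 per the sphingolipid C26), attached to a glycerol-3-phosphate or
DHAP backbone (sn1 any chain, sn2 unsaturated) to give lysoPA and then PA.
CTP activation yields CDP-DG, the branch point to PI, PS (then PE, then PC)
and cardiolipin.  PA also interconverts with DAG, which is acylated to the
storage lipid TAG; the lumped sterol branch spends 18 acetyl-CoA per
ergosterol and esterifies it to SE; the lumped sphingolipid branch combines a
ceramide precursor with the head group of a PI (releasing the PI's
diacylglycerol).  The TAG lipase and SE hydrolase mobilize the storage lipids
and are active only after G1, mirroring their cell-cycle-dependent activation.

The scavenging (Kennedy) route for PE/PC from external precursors is
deliberately absent: the model covers de novo synthesis only.
"""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_FA_WEIGHTS, ReactionParameters, SimulationConfig
from .engine import Reaction
from .lipids import (
    ACETYL_PER_CHAIN,
    ACETYL_PER_ERGOSTEROL,
    COMMON_FATTY_ACIDS,
    C26_0,
    LipidClass,
)
from .state import CellState, draw_without_replacement, UNSATURATED_INDICES

__all__ = ["build_network", "REACTION_TYPES", "species_graph"]

#: acetyl-CoA cost per common chain species, aligned with COMMON_FATTY_ACIDS.
_ACETYL_COST = np.array([ACETYL_PER_CHAIN[fa] for fa in COMMON_FATTY_ACIDS])
_ACETYL_COST_MAX = int(_ACETYL_COST.max())
_ACETYL_PER_C26 = ACETYL_PER_CHAIN[C26_0]
_N_SN2 = len(UNSATURATED_INDICES)  # 2
_N_FA = len(COMMON_FATTY_ACIDS)  # 4


def _expand(counts: np.ndarray) -> np.ndarray:
    """Expand a count vector into an array of item indices."""
    return np.repeat(np.arange(len(counts)), counts)


def _random_pairing(
    counts_a: np.ndarray, counts_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random pairing of two equal-size selected multisets."""
    ia = _expand(counts_a)
    ib = _expand(counts_b)
    rng.shuffle(ib)
    return ia, ib


# ---------------------------------------------------------------------------
# precursor-producing rules
# ---------------------------------------------------------------------------

class AcetylCoASynthase(Reaction):
    """pyruvate -> acetyl-CoA (lumped pyruvate dehydrogenase/ACS step)."""

    required_substrates = ("pyruvate",)

    def capacity(self, state: CellState) -> int:
        return state.pools.available("pyruvate")

    def _apply_batch(self, state, k, rng):
        state.pools.consume("pyruvate", k)
        state.pools.add("acetyl_coa", k)


class InositolSynthase(Reaction):
    """glucose 6-phosphate -> inositol (lumped INO1/IMPase)."""

    required_substrates = ("glucose_6_p",)

    def capacity(self, state):
        return state.pools.available("glucose_6_p")

    def _apply_batch(self, state, k, rng):
        state.pools.consume("glucose_6_p", k)
        state.pools.add("inositol", k)


class FattyAcidSynthase(Reaction):
    """acetyl-CoA -> activated acyl chain; species drawn from fa_weights.

    Desaturation is folded into the categorical draw; a C16 chain costs 8
    acetyl-CoA units, a C18 chain 9.
    """

    required_substrates = ("acetyl_coa",)

    def __init__(self, name, params):
        super().__init__(name, params)
        self.weights = np.asarray(params.fa_weights or DEFAULT_FA_WEIGHTS)

    def capacity(self, state):
        # conservative bound with the most expensive chain, so a batch can
        # never overdraw the pool
        return state.pools.available("acetyl_coa", _ACETYL_COST_MAX)

    def _apply_batch(self, state, k, rng):
        species = rng.multinomial(k, self.weights)
        cost = int(species @ _ACETYL_COST)
        state.pools.consume("acetyl_coa", cost)
        state.free_fatty_acids += species
        state.produced_chains[:_N_FA] += species


# ---------------------------------------------------------------------------
# glycerolipid backbone assembly
# ---------------------------------------------------------------------------

class LysoPASynthase(Reaction):
    """backbone (G3P or DHAP) + fatty acid -> lysoPA (sn1 acylation)."""

    def __init__(self, name, params, backbone: str):
        self.backbone = backbone
        self.required_substrates = (backbone, "fatty_acid")
        super().__init__(name, params)

    def capacity(self, state):
        return min(state.pools.available(self.backbone),
                   int(state.free_fatty_acids.sum()))

    def _apply_batch(self, state, k, rng):
        state.pools.consume(self.backbone, k)
        selected = draw_without_replacement(state.free_fatty_acids, k, rng)
        state.free_fatty_acids -= selected
        state.free_lipids[LipidClass.LYSO_PA] += selected


class PASynthase(Reaction):
    """lysoPA + unsaturated fatty acid -> PA (sn2 acylation).

    The sn2 position accepts only unsaturated chains; with no unsaturated
    chain available the acylation no-ops.
    """

    required_substrates = ("lysoPA", "unsaturated_fatty_acid")

    def capacity(self, state):
        return min(state.free_total(LipidClass.LYSO_PA), state.free_unsaturated_fa())

    def _apply_batch(self, state, k, rng):
        lyso = draw_without_replacement(state.free_lipids[LipidClass.LYSO_PA], k, rng)
        state.free_lipids[LipidClass.LYSO_PA] -= lyso
        unsat_pool = state.free_fatty_acids[UNSATURATED_INDICES]
        sn2 = draw_without_replacement(unsat_pool, k, rng)
        state.free_fatty_acids[UNSATURATED_INDICES] -= sn2
        sn1_idx, sn2_idx = _random_pairing(lyso, sn2, rng)
        np.add.at(state.free_lipids[LipidClass.PA], sn1_idx * _N_SN2 + sn2_idx, 1)


# ---------------------------------------------------------------------------
# head-group chemistry (the 8-composition diacyl space is shared, so these
# moves are index-preserving: head-group edits never touch the chains)
# ---------------------------------------------------------------------------

class HeadgroupConversion(Reaction):
    """substrate class -> product class, optionally consuming a precursor and
    releasing a small byproduct; acyl chains are carried over unchanged."""

    source: LipidClass
    target: LipidClass
    precursor: str | None = None
    byproduct: str | None = None

    def __init__(self, name, params):
        self.required_substrates = (
            (self.source.value,) if self.precursor is None
            else (self.source.value, self.precursor)
        )
        super().__init__(name, params)

    def capacity(self, state):
        avail = state.free_total(self.source)
        if self.precursor is not None:
            avail = min(avail, state.pools.available(self.precursor))
        return avail

    def _apply_batch(self, state, k, rng):
        selected = draw_without_replacement(state.free_lipids[self.source], k, rng)
        state.free_lipids[self.source] -= selected
        state.free_lipids[self.target] += selected
        if self.precursor is not None:
            state.pools.consume(self.precursor, k)
        if self.byproduct is not None:
            state.release_byproduct(self.byproduct, k)


class CDPDGSynthase(HeadgroupConversion):
    """PA + CTP -> CDP-DG: CTP attachment activates the PA head group."""
    source, target, precursor = LipidClass.PA, LipidClass.CDP_DG, "ctp"


class PSSynthase(HeadgroupConversion):
    """CDP-DG + serine -> PS, releasing CMP."""
    source, target, precursor, byproduct = (
        LipidClass.CDP_DG, LipidClass.PS, "serine", "CMP")


class PISynthase(HeadgroupConversion):
    """CDP-DG + inositol -> PI, releasing CMP."""
    source, target, precursor, byproduct = (
        LipidClass.CDP_DG, LipidClass.PI, "inositol", "CMP")


class PSDecarboxylase(HeadgroupConversion):
    """PS -> PE (head-group decarboxylation)."""
    source, target, byproduct = LipidClass.PS, LipidClass.PE, "CO2"


class PCSynthase(HeadgroupConversion):
    """PE -> PC (lumped triple methylation; methyl donors untracked)."""
    source, target = LipidClass.PE, LipidClass.PC


class PAPhosphatase(HeadgroupConversion):
    """PA -> DAG, releasing phosphate."""
    source, target, byproduct = LipidClass.PA, LipidClass.DAG, "Pi"


class DAGKinase(HeadgroupConversion):
    """DAG + CTP -> PA (re-activation of DAG)."""
    source, target, precursor = LipidClass.DAG, LipidClass.PA, "ctp"


class CLSynthase(Reaction):
    """2 CDP-DG + glycerol-3-phosphate -> cardiolipin (lumped CL branch).

    The CL object carries the four acyl chains of its two CDP-DG donors.
    """

    required_substrates = ("CDP_DG", "glycerol_3_p")

    def capacity(self, state):
        return min(state.free_total(LipidClass.CDP_DG) // 2,
                   state.pools.available("glycerol_3_p"))

    def _apply_batch(self, state, k, rng):
        selected = draw_without_replacement(
            state.free_lipids[LipidClass.CDP_DG], 2 * k, rng)
        state.free_lipids[LipidClass.CDP_DG] -= selected
        state.pools.consume("glycerol_3_p", k)
        items = _expand(selected)
        rng.shuffle(items)
        first, second = items[:k], items[k:]
        np.add.at(state.free_lipids[LipidClass.CL], first * 8 + second, 1)
        state.release_byproduct("CMP", 2 * k)


# ---------------------------------------------------------------------------
# storage lipids
# ---------------------------------------------------------------------------

class TAGSynthase(Reaction):
    """DAG + fatty acid -> TAG (sn3 acylation; any chain species)."""

    required_substrates = ("DAG", "fatty_acid")

    def capacity(self, state):
        return min(state.free_total(LipidClass.DAG),
                   int(state.free_fatty_acids.sum()))

    def _apply_batch(self, state, k, rng):
        dag = draw_without_replacement(state.free_lipids[LipidClass.DAG], k, rng)
        state.free_lipids[LipidClass.DAG] -= dag
        fa = draw_without_replacement(state.free_fatty_acids, k, rng)
        state.free_fatty_acids -= fa
        dag_idx, fa_idx = _random_pairing(dag, fa, rng)
        np.add.at(state.free_lipids[LipidClass.TAG], dag_idx * _N_FA + fa_idx, 1)


class TAGLipase(Reaction):
    """TAG -> DAG + free fatty acid (Tgl4-style mobilization, post-G1)."""

    required_substrates = ("TAG",)

    def capacity(self, state):
        return state.free_total(LipidClass.TAG)

    def _apply_batch(self, state, k, rng):
        selected = draw_without_replacement(state.free_lipids[LipidClass.TAG], k, rng)
        state.free_lipids[LipidClass.TAG] -= selected
        table = selected.reshape(len(state.free_lipids[LipidClass.DAG]), _N_FA)
        state.free_lipids[LipidClass.DAG] += table.sum(axis=1)
        state.free_fatty_acids += table.sum(axis=0)


class ErgosterolSynthase(Reaction):
    """18 acetyl-CoA -> ergosterol (the >15-step pathway, lumped)."""

    required_substrates = ("acetyl_coa",)

    def capacity(self, state):
        return state.pools.available("acetyl_coa", ACETYL_PER_ERGOSTEROL)

    def _apply_batch(self, state, k, rng):
        state.pools.consume("acetyl_coa", ACETYL_PER_ERGOSTEROL * k)
        state.free_lipids[LipidClass.ES][0] += k
        state.produced_es += k


class SESynthase(Reaction):
    """ergosterol + fatty acid -> steryl ester (storage form)."""

    required_substrates = ("ES", "fatty_acid")

    def capacity(self, state):
        return min(state.free_total(LipidClass.ES),
                   int(state.free_fatty_acids.sum()))

    def _apply_batch(self, state, k, rng):
        state.free_lipids[LipidClass.ES][0] -= k
        fa = draw_without_replacement(state.free_fatty_acids, k, rng)
        state.free_fatty_acids -= fa
        state.free_lipids[LipidClass.SE] += fa


class SEHydrolase(Reaction):
    """steryl ester -> ergosterol + fatty acid (post-G1 mobilization)."""

    required_substrates = ("SE",)

    def capacity(self, state):
        return state.free_total(LipidClass.SE)

    def _apply_batch(self, state, k, rng):
        selected = draw_without_replacement(state.free_lipids[LipidClass.SE], k, rng)
        state.free_lipids[LipidClass.SE] -= selected
        state.free_fatty_acids += selected
        state.free_lipids[LipidClass.ES][0] += k


class SphingolipidSynthase(Reaction):
    """ceramide + PI -> sphingolipid (+ DAG), the lumped MIPC route.

    The inositol-phosphate head group of a PI is transferred onto a ceramide
    backbone whose C26:0 chain costs 13 acetyl-CoA units; the PI's
    diacylglycerol is released back into the free DAG pool, so no acyl chains
    are destroyed.
    """

    required_substrates = ("ceramide", "PI")

    def capacity(self, state):
        return min(state.pools.available("ceramide"),
                   state.free_total(LipidClass.PI),
                   state.pools.available("acetyl_coa", _ACETYL_PER_C26))

    def _apply_batch(self, state, k, rng):
        state.pools.consume("ceramide", k)
        state.pools.consume("acetyl_coa", _ACETYL_PER_C26 * k)
        selected = draw_without_replacement(state.free_lipids[LipidClass.PI], k, rng)
        state.free_lipids[LipidClass.PI] -= selected
        state.free_lipids[LipidClass.DAG] += selected
        state.free_lipids[LipidClass.SL][0] += k
        state.produced_chains[_N_FA] += k  # the C26:0 chains


# ---------------------------------------------------------------------------

REACTION_TYPES: dict[str, type[Reaction] | tuple] = {
    "acetyl_coa_synthase": AcetylCoASynthase,
    "inositol_synthase": InositolSynthase,
    "fatty_acid_synthase": FattyAcidSynthase,
    "lyso_pa_synthase_g3p": (LysoPASynthase, {"backbone": "glycerol_3_p"}),
    "lyso_pa_synthase_dhap": (LysoPASynthase, {"backbone": "dhap"}),
    "pa_synthase": PASynthase,
    "cdp_dg_synthase": CDPDGSynthase,
    "ps_synthase": PSSynthase,
    "pi_synthase": PISynthase,
    "cl_synthase": CLSynthase,
    "ps_decarboxylase": PSDecarboxylase,
    "pc_synthase": PCSynthase,
    "pa_phosphatase": PAPhosphatase,
    "dag_kinase": DAGKinase,
    "tag_synthase": TAGSynthase,
    "tag_lipase": TAGLipase,
    "ergosterol_synthase": ErgosterolSynthase,
    "se_synthase": SESynthase,
    "se_hydrolase": SEHydrolase,
    "sphingolipid_synthase": SphingolipidSynthase,
}


def build_network(config: SimulationConfig) -> list[Reaction]:
    """Instantiate the reaction rules from the configured parameters."""
    reactions: list[Reaction] = []
    for name, params in config.reactions.items():
        if name not in REACTION_TYPES:
            raise KeyError(
                f"unknown reaction '{name}'; valid names: "
                f"{sorted(REACTION_TYPES)}"
            )
        entry = REACTION_TYPES[name]
        if isinstance(entry, tuple):
            cls, kwargs = entry
            reactions.append(cls(name, params, **kwargs))
        else:
            reactions.append(entry(name, params))
    return reactions


#: species-level edges of the network, for topology checks and documentation.
_SPECIES_EDGES: tuple[tuple[str, str], ...] = (
    ("pyruvate", "acetyl_coa"),
    ("glucose_6_p", "inositol"),
    ("acetyl_coa", "fatty_acid"),
    ("glycerol_3_p", "lysoPA"), ("dhap", "lysoPA"), ("fatty_acid", "lysoPA"),
    ("lysoPA", "PA"), ("fatty_acid", "PA"),
    ("PA", "CDP_DG"), ("ctp", "CDP_DG"),
    ("CDP_DG", "PI"), ("inositol", "PI"),
    ("CDP_DG", "PS"), ("serine", "PS"),
    ("CDP_DG", "CL"), ("glycerol_3_p", "CL"),
    ("PS", "PE"), ("PE", "PC"),
    ("PA", "DAG"), ("DAG", "PA"),
    ("DAG", "TAG"), ("fatty_acid", "TAG"), ("TAG", "DAG"),
    ("acetyl_coa", "ES"), ("ES", "SE"), ("fatty_acid", "SE"), ("SE", "ES"),
    ("ceramide", "SL"), ("PI", "SL"),
)


def species_graph() -> dict[str, set[str]]:
    """Directed species graph of the network (adjacency sets)."""
    graph: dict[str, set[str]] = {}
    for src, dst in _SPECIES_EDGES:
        graph.setdefault(src, set()).add(dst)
        graph.setdefault(dst, set())
    return graph
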