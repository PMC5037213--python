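"""Mutable simulation state: precursor pools, membranes and the full cell.

Lipids of identical (class, chain composition) are exchangeable, so the state
stores integer count vectors over each class's enumerated chain-composition
space (`lipids.CHAIN_SPACE`) instead of retaining individual objects.  Free
lipids live in per-class vectors on the cell state; membranes hold per-class
tally vectors and act as absorbing sinks (only the lipid droplet releases
content again).  Uniform random selection of k objects from a pool is then a
multivariate-hypergeometric draw over the composition vector, which is
distribution-identical to removing k uniformly random objects one by one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lipids import (
    CHAIN_SPACE,
    COMMON_FATTY_ACIDS,
    LipidClass,
    MEMBRANE_CLASSES,
    SPACE_SIZE,
)

__all__ = [
    "PrecursorPool",
    "Membrane",
    "CellState",
    "composition_fractions",
    "EmptyMembraneError",
    "stochastic_round",
    "draw_without_replacement",
]

#: Indices of the unsaturated species within COMMON_FATTY_ACIDS.
UNSATURATED_INDICES = np.array(
    [i for i, fa in enumerate(COMMON_FATTY_ACIDS) if fa.unsaturated], dtype=np.intp
)


class EmptyMembraneError(ValueError):
    """Composition of an empty membrane is undefined."""


def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Round x to an integer without systematic bias: floor(x) + Bernoulli(frac)."""
    low = int(np.floor(x))
    frac = x - low
    if frac > 0 and rng.random() < frac:
        low += 1
    return low


def draw_without_replacement(
    counts: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Select k objects uniformly without replacement from a count vector."""
    total = int(counts.sum())
    if k >= total:
        return counts.copy()
    if k <= 0:
        return np.zeros_like(counts)
    return rng.multivariate_hypergeometric(counts, k).astype(counts.dtype)


@dataclass
class PrecursorPool:
    """Small-molecule precursor pools with constant per-step refill.

    Counts are model units (10^4 molecules); refill rates may be fractional
    and are applied exactly, so pools are stored as floats while consumption
    is integer-valued.  `consumed` accumulates total consumption per pool
    (the carbon ledger uses the acetyl-CoA entry).
    """

    counts: dict[str, float]
    refill_rates: dict[str, float]
    extra_refill: dict[str, float] = field(default_factory=dict)
    consumed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pool in self.counts:
            self.consumed.setdefault(pool, 0.0)

    def available(self, pool: str, stoichiometry: int = 1) -> int:
        """How many reaction executions the pool can support."""
        return int(self.counts[pool] // stoichiometry)

    def consume(self, pool: str, amount: float) -> None:
        if amount < 0 or amount > self.counts[pool] + 1e-9:
            raise ValueError(f"cannot consume {amount} from pool {pool}")
        self.counts[pool] -= amount
        self.consumed[pool] += amount

    def add(self, pool: str, amount: float) -> None:
        self.counts[pool] += amount

    def refill(self) -> None:
        """Replenish every pool by its configured rate plus supplementation."""
        for pool, rate in self.refill_rates.items():
            self.counts[pool] += rate
        for pool, rate in self.extra_refill.items():
            self.counts[pool] += rate


def _empty_tallies() -> dict[LipidClass, np.ndarray]:
    return {cls: np.zeros(SPACE_SIZE[cls], dtype=np.int64) for cls in MEMBRANE_CLASSES}


@dataclass
class Membrane:
    """One subcellular membrane: per-(class, composition) lipid tallies.

    Membranes are absorbing: lipids cannot leave once incorporated.  The lipid
    droplet is the exception and is handled by the droplet flux stage.
    """

    identity: str
    composition_target: dict[LipidClass, float]
    size_weight: float
    lipid_counts: dict[LipidClass, np.ndarray] = field(default_factory=_empty_tallies)

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.lipid_counts.values()))

    def class_counts(self) -> dict[LipidClass, int]:
        return {cls: int(v.sum()) for cls, v in self.lipid_counts.items()}

    def add(self, lipid_class: LipidClass, composition_counts: np.ndarray) -> None:
        self.lipid_counts[lipid_class] += composition_counts

    def remove(self, lipid_class: LipidClass, composition_counts: np.ndarray) -> None:
        tally = self.lipid_counts[lipid_class]
        if np.any(composition_counts > tally):
            raise ValueError(f"removing more {lipid_class} than present in {self.identity}")
        tally -= composition_counts


def composition_fractions(membrane: Membrane) -> dict[LipidClass, float]:
    """Relative contribution of each lipid class to a membrane's lipid count.

    Raises EmptyMembraneError for an empty membrane (fractions undefined).
    """
    total = membrane.total()
    if total == 0:
        raise EmptyMembraneError(f"membrane {membrane.identity} holds no lipids")
    return {cls: count / total for cls, count in membrane.class_counts().items()}


@dataclass
class CellState:
    """Full cell state at one instant of the simulated cell cycle."""

    t: float
    phase: str
    pools: PrecursorPool
    #: free (not yet esterified) fatty-acid chains over COMMON_FATTY_ACIDS.
    free_fatty_acids: np.ndarray
    #: free lipid objects per class, as composition count vectors.
    free_lipids: dict[LipidClass, np.ndarray]
    membranes: dict[str, Membrane]
    rng: np.random.Generator
    #: small molecules released by reactions (CMP etc.), diagnostic only.
    byproducts: dict[str, float] = field(default_factory=dict)
    #: chains ever synthesized, per species of lipids.ALL_FATTY_ACIDS.
    produced_chains: np.ndarray = field(default_factory=lambda: np.zeros(5, dtype=np.int64))
    #: ergosterol molecules ever synthesized.
    produced_es: int = 0

    # ------------------------------------------------------------------
    def free_total(self, lipid_class: LipidClass) -> int:
        return int(self.free_lipids[lipid_class].sum())

    def free_unsaturated_fa(self) -> int:
        return int(self.free_fatty_acids[UNSATURATED_INDICES].sum())

    def release_byproduct(self, name: str, amount: float = 1.0) -> None:
        self.byproducts[name] = self.byproducts.get(name, 0.0) + amount

    @property
    def carbon_ledger(self) -> dict[str, float]:
        """Cumulative precursor consumption (carbon-conservation bookkeeping)."""
        return dict(self.pools.consumed)

    def total_membrane_lipids(self) -> int:
        return sum(m.total() for m in self.membranes.values())

    def total_free_lipids(self) -> int:
        return int(sum(int(v.sum()) for v in self.free_lipids.values()))


def empty_free_pools() -> dict[LipidClass, np.ndarray]:
    """Zeroed free-lipid vectors for every class that can occur free."""
    return {cls: np.zeros(len(CHAIN_SPACE[cls]), dtype=np.int64) for cls in LipidClass}
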