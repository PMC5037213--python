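"""Transport of free lipids to membranes, droplet fluxes, cell-cycle clock.

Each step, a fixed fraction (default 10%) of every free membrane-lipid class
is distributed to the eight bilayer membranes.  The destination probabilities
are products of membrane size weights and the membrane's composition target
for that class, renormalized per class, so a class never enters a membrane
whose target fraction for it is zero.  Membranes are absorbing sinks; only
the lipid droplet exchanges material with the free pools, via constant
phase-dependent fluxes: TAG and steryl esters flow in during G1 (50:50) and
back out from S phase on, until the droplet is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MEMBRANE_NAMES, SimulationConfig
from .lipids import LipidClass, MEMBRANE_CLASSES
from .state import CellState, draw_without_replacement, stochastic_round

__all__ = ["TransportMatrix", "distribute", "droplet_flux", "phase_of"]

#: membranes reachable by the transport stage (all but the droplet).
BILAYER_MEMBRANES: tuple[str, ...] = tuple(
    name for name in MEMBRANE_NAMES if name != "lipid_droplet"
)

#: the two storage classes exchanged with the droplet.
DROPLET_CLASSES = (LipidClass.TAG, LipidClass.SE)


@dataclass(frozen=True)
class TransportMatrix:
    """Per-class destination weights over the bilayer membranes.

    weight(class, membrane) ~ size_weight(membrane) x composition_target
    (membrane, class), renormalized so each class's row sums to 1.  A class
    whose weights vanish everywhere (e.g. an intermediate) is not transported.
    """

    membranes: tuple[str, ...]
    weights: dict[LipidClass, np.ndarray | None]

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "TransportMatrix":
        weights: dict[LipidClass, np.ndarray | None] = {}
        for lipid_class in MEMBRANE_CLASSES:
            row = np.array([
                config.membranes[name].size_weight
                * config.membranes[name].composition_target.get(lipid_class.value, 0.0)
                for name in BILAYER_MEMBRANES
            ])
            total = row.sum()
            weights[lipid_class] = row / total if total > 0 else None
        return cls(membranes=BILAYER_MEMBRANES, weights=weights)


def distribute(
    state: CellState,
    matrix: TransportMatrix,
    fraction: float,
    rng: np.random.Generator,
) -> CellState:
    """Move a fraction of every free lipid class into the membranes.

    The number moved per class is the (stochastically rounded) fraction of
    the pool; the objects are selected uniformly and each is assigned a
    membrane drawn from the class's weight row.  The rounding is unbiased so
    small pools are not systematically stranded.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("transport fraction must lie in [0, 1]")
    if fraction == 0.0:
        return state
    for lipid_class in MEMBRANE_CLASSES:
        row = matrix.weights[lipid_class]
        if row is None:
            continue
        pool = state.free_lipids[lipid_class]
        total = int(pool.sum())
        if total == 0:
            continue
        n_move = min(stochastic_round(fraction * total, rng), total)
        if n_move == 0:
            continue
        selected = draw_without_replacement(pool, n_move, rng)
        pool -= selected
        # each selected object independently draws its destination membrane
        allocation = rng.multinomial(selected, row)  # (n_compositions, n_membranes)
        for j, name in enumerate(matrix.membranes):
            column = allocation[:, j]
            if column.any():
                state.membranes[name].add(lipid_class, column)
    return state


def droplet_flux(
    state: CellState, config: SimulationConfig, rng: np.random.Generator
) -> CellState:
    """Phase-dependent constant TAG/SE exchange between droplet and free pools.

    During G1 a constant number of TAG and SE per step (a 50:50 mix) moves
    from the free pools into the droplet, limited by availability; after G1
    the flux reverses until the droplet is empty.
    """
    droplet = state.membranes["lipid_droplet"]
    if state.phase == "G1":
        for lipid_class in DROPLET_CLASSES:
            pool = state.free_lipids[lipid_class]
            amount = min(stochastic_round(config.droplet_influx, rng), int(pool.sum()))
            if amount <= 0:
                continue
            selected = draw_without_replacement(pool, amount, rng)
            pool -= selected
            droplet.add(lipid_class, selected)
    else:
        for lipid_class in DROPLET_CLASSES:
            tally = droplet.lipid_counts[lipid_class]
            amount = min(stochastic_round(config.droplet_efflux, rng), int(tally.sum()))
            if amount <= 0:
                continue
            selected = draw_without_replacement(tally, amount, rng)
            droplet.remove(lipid_class, selected)
            state.free_lipids[lipid_class] += selected
    return state


def phase_of(t: float, config: SimulationConfig) -> str:
    """Cell-cycle phase at time t (seconds); G1 ends at config.g1_end."""
    if t < 0 or t > config.horizon:
        raise ValueError(f"t={t} outside the simulated cell cycle")
    if t < config.g1_end:
        return "G1"
    if t < config.s_end:
        return "S"
    if t < config.g2_end:
        return "G2"
    return "M"
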