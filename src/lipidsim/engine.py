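"""Hybrid stochastic execution protocol.

Each reaction rule carries a maximum number of executions per time step
(``n_max``, the stochastic analogue of vmax) and fires with a probability
derived from substrate saturation, in analogy to the Michaelis-Menten rate
law:

    p = [S] / (Km + [S])            (one factor per substrate)

Per 1 s step the protocol is: (1) evaluate every reaction's probability from
the state at the start of the step; (2) randomly permute the reaction order;
(3) for each reaction draw the number of executions k ~ Binomial(n_max, p) and
apply them; (4) replenish the precursor pools; (5) run the transport stage.
The binomial draw is distribution-identical to the literal protocol of drawing
n_max uniform numbers and executing once per number below p; the literal loop
is kept as `draw_executions_loop` for cross-checking.  Executions that find
their substrates exhausted (consumed earlier in the same step) are silent
no-ops, as in tau-leaping with post-hoc clipping.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigurationError, ReactionParameters, SimulationConfig
from .lipids import LipidClass
from .state import CellState

__all__ = [
    "substrate_saturation",
    "reaction_probability",
    "draw_executions",
    "draw_executions_loop",
    "Reaction",
    "apply_reaction_once",
    "step",
]


def substrate_saturation(count: float, km: float) -> float:
    """Saturation probability count/(km + count) of a single substrate."""
    if km <= 0:
        raise ValueError("km must be > 0")
    if count < 0:
        raise ValueError("substrate count must be >= 0")
    return count / (km + count)


def substrate_level(state: CellState, substrate: str) -> float:
    """Current count of a named substrate (precursor pool, free-lipid class,
    or the free fatty-acid pools)."""
    if substrate in state.pools.counts:
        return state.pools.counts[substrate]
    if substrate == "fatty_acid":
        return float(state.free_fatty_acids.sum())
    if substrate == "unsaturated_fatty_acid":
        return float(state.free_unsaturated_fa())
    return float(state.free_total(LipidClass(substrate)))


class Reaction:
    """A reaction rule: substrate classes, transformation, kinetic parameters.

    Subclasses define `required_substrates` (the substrates entering the
    probability product), `capacity` (how many executions current pools can
    support) and `_apply_batch` (the actual transformation for a batch of k
    executions).  A missing Km for a required substrate is a configuration
    error raised at construction, not at runtime.
    """

    #: substrate names entering the saturation product.
    required_substrates: tuple[str, ...] = ()

    def __init__(self, name: str, params: ReactionParameters):
        self.name = name
        self.params = params
        for substrate in self.required_substrates:
            if substrate not in params.km:
                raise ConfigurationError(
                    f"reaction '{name}' lacks a Km for substrate '{substrate}'"
                )

    def active_in(self, phase: str) -> bool:
        return self.params.phases is None or phase in self.params.phases

    # -- to implement ----------------------------------------------------
    def capacity(self, state: CellState) -> int:
        """Maximum executions the current substrate pools can support."""
        raise NotImplementedError

    def _apply_batch(self, state: CellState, k: int, rng: np.random.Generator) -> None:
        raise NotImplementedError

    # --------------------------------------------------------------------
    def apply(self, state: CellState, k: int, rng: np.random.Generator) -> int:
        """Execute the rule up to k times (batched); returns executions done.

        Substrate availability is re-checked at execution time: executions
        beyond the available substrate are silent no-ops.
        """
        k_eff = min(int(k), self.capacity(state))
        if k_eff > 0:
            self._apply_batch(state, k_eff, rng)
        return max(k_eff, 0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Reaction {self.name} n_max={self.params.n_max}>"


def reaction_probability(reaction: Reaction, state: CellState) -> float:
    """Product of per-substrate saturation terms, from the current state."""
    p = 1.0
    for substrate in reaction.required_substrates:
        p *= substrate_saturation(
            substrate_level(state, substrate), reaction.params.km[substrate]
        )
    return p


def draw_executions(n_max: int, p: float, rng: np.random.Generator) -> int:
    """Number of executions in one step: k ~ Binomial(n_max, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if n_max == 0 or p == 0.0:
        return 0
    return int(rng.binomial(n_max, p))


def draw_executions_loop(n_max: int, p: float, rng: np.random.Generator) -> int:
    """Literal protocol: draw n_max uniforms, execute once per u < p.

    Reference implementation used to validate the binomial shortcut.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return int(np.count_nonzero(rng.random(int(n_max)) < p))


def apply_reaction_once(
    reaction: Reaction, state: CellState, rng: np.random.Generator
) -> bool:
    """Apply a single execution of a rule to the state.

    A uniformly random eligible substrate object is taken from its list,
    transformed and appended to the product pool; precursor pools are
    decremented.  If substrates are exhausted, the call is a silent no-op and
    returns False.
    """
    return reaction.apply(state, 1, rng) == 1


def step(
    state: CellState,
    reactions: list[Reaction],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    transport_matrix=None,
) -> CellState:
    """Advance the state by one time step (mutates and returns it)."""
    from . import transport as _transport

    if rng is None:
        rng = state.rng
    if transport_matrix is None:
        transport_matrix = _transport.TransportMatrix.from_config(config)

    # (1) probabilities from the start-of-step state
    probs = [
        reaction_probability(r, state) if r.active_in(state.phase) else 0.0
        for r in reactions
    ]
    # (2) randomized reaction order; (3) thresholded executions
    for i in rng.permutation(len(reactions)):
        r = reactions[i]
        k = draw_executions(r.params.n_max, probs[i], rng)
        if k > 0:
            r.apply(state, k, rng)
    # (4) precursor refill
    state.pools.refill()
    # (5) transport stage: membrane distribution and droplet fluxes
    _transport.distribute(state, transport_matrix, config.transport_fraction, rng)
    _transport.droplet_flux(state, config, rng)

    state.t += config.dt
    state.phase = _transport.phase_of(min(state.t, config.horizon), config)
    return state
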