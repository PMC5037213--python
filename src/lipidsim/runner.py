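"""Initialization, main loop, ensemble driver and trajectory records.

A run initializes a cell in early G1 from the configured membrane sizes and
composition targets (with a small multiplicative noise so every simulated
cell starts slightly different), then advances the state in 1 s steps over
the 120-min cycle, recording membrane sizes at a configurable sampling
interval.  Ensembles derive per-run seeds from a master seed via a counter,
so any individual run can be re-extracted bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MEMBRANE_NAMES, SimulationConfig, default_config
from .engine import step
from .lipids import CHAIN_SPACE, LipidClass, MEMBRANE_CLASSES
from .network import build_network
from .state import CellState, Membrane, PrecursorPool, empty_free_pools
from .transport import TransportMatrix, phase_of

__all__ = ["initialize", "run", "run_ensemble", "Trajectory", "EnsembleResult"]


# ---------------------------------------------------------------------------
# chain-composition probabilities used to seed initial lipids
# ---------------------------------------------------------------------------

def _position_distributions(fa_weights) -> tuple[np.ndarray, np.ndarray]:
    """Per-position chain distributions whose two-position average equals the
    target fatty-acid distribution.

    sn2 carries the unsaturated species with renormalized target weights; sn1
    compensates (sn1 = 2*target - sn2marginal, clipped) so a diacyl lipid's
    chain pool matches the target overall.
    """
    t = np.asarray(fa_weights, dtype=float)
    sn2 = np.zeros(4)
    unsat = np.array([1, 3])  # C16:1, C18:1
    sn2[unsat] = t[unsat] / t[unsat].sum()
    sn1 = np.clip(2.0 * t - sn2, 0.0, None)
    sn1 /= sn1.sum()
    return sn1, sn2


def composition_probabilities(fa_weights) -> dict[LipidClass, np.ndarray]:
    """Probability vector over each class's chain space for initialization."""
    t = np.asarray(fa_weights, dtype=float)
    sn1, sn2 = _position_distributions(t)
    sn2u = sn2[np.array([1, 3])]  # over the two unsaturated choices
    diacyl = np.outer(sn1, sn2u).ravel()
    probs: dict[LipidClass, np.ndarray] = {}
    for cls in LipidClass:
        n = len(CHAIN_SPACE[cls])
        if n == 1:
            probs[cls] = np.ones(1)
        elif cls in (LipidClass.LYSO_PA, LipidClass.SE):
            probs[cls] = t.copy()
        elif cls is LipidClass.TAG:
            probs[cls] = np.outer(diacyl, t).ravel()
        elif cls is LipidClass.CL:
            probs[cls] = np.outer(diacyl, diacyl).ravel()
        else:
            probs[cls] = diacyl.copy()
    return probs


def initialize(config: SimulationConfig, rng: np.random.Generator) -> CellState:
    """Produce the early-G1 cell: membranes, free pools and precursors.

    Membrane counts are the configured initial sizes perturbed by a uniform
    relative noise of amplitude ``init_noise``; class tallies are multinomial
    draws from the composition targets, and chain compositions follow the
    configured fatty-acid distribution with the sn2-unsaturation constraint.
    """
    config.validate()
    fa_weights = config.reactions["fatty_acid_synthase"].fa_weights
    comp_probs = composition_probabilities(fa_weights)

    membranes: dict[str, Membrane] = {}
    class_order = list(MEMBRANE_CLASSES)
    for name in MEMBRANE_NAMES:
        mem_cfg = config.membranes[name]
        noise = rng.uniform(-config.init_noise, config.init_noise)
        count = int(round(mem_cfg.initial_count * (1.0 + noise)))
        if count < 0:
            warnings.warn(f"negative initial count for {name}; clipped to 0")
            count = 0
        target = np.array([
            mem_cfg.composition_target.get(cls.value, 0.0) for cls in class_order
        ])
        per_class = rng.multinomial(count, target / target.sum()) if count else \
            np.zeros(len(class_order), dtype=np.int64)
        membrane = Membrane(
            identity=name,
            composition_target={
                cls: mem_cfg.composition_target.get(cls.value, 0.0)
                for cls in class_order
            },
            size_weight=mem_cfg.size_weight,
        )
        for cls, n_class in zip(class_order, per_class):
            if n_class:
                membrane.lipid_counts[cls] += rng.multinomial(n_class, comp_probs[cls])
        membranes[name] = membrane

    free = empty_free_pools()
    bilayers = [m for n, m in membranes.items() if n != "lipid_droplet"]
    for cls in MEMBRANE_CLASSES:
        resident = sum(int(m.lipid_counts[cls].sum()) for m in bilayers)
        n_free = int(round(config.free_pool_fraction * resident))
        if n_free:
            free[cls] += rng.multinomial(n_free, comp_probs[cls])
    for cls_name, amount in config.initial_free_intermediates.items():
        cls = LipidClass(cls_name)
        n_free = int(round(amount))
        if n_free:
            free[cls] += rng.multinomial(n_free, comp_probs[cls])

    n_fa = int(round(config.initial_free_fatty_acids))
    free_fa = rng.multinomial(n_fa, np.asarray(fa_weights)) if n_fa else \
        np.zeros(4, dtype=np.int64)

    pools = PrecursorPool(
        counts=dict(config.pools.initial),
        refill_rates=dict(config.pools.refill),
        extra_refill=dict(config.pools.extra_refill),
    )
    return CellState(
        t=0.0,
        phase=phase_of(0.0, config),
        pools=pools,
        free_fatty_acids=free_fa.astype(np.int64),
        free_lipids=free,
        membranes=membranes,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled time series of one simulation run."""

    times: np.ndarray
    membrane_counts: dict[str, np.ndarray]
    free_lipid_totals: np.ndarray
    acetyl_consumed: np.ndarray
    final_state: CellState
    seed: object = None

    def final_counts(self) -> dict[str, int]:
        return {name: int(series[-1]) for name, series in self.membrane_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_s, membrane, lipid_count) for TSV export."""
        records = [
            (t, name, int(self.membrane_counts[name][i]))
            for i, t in enumerate(self.times)
            for name in MEMBRANE_NAMES
        ]
        return pd.DataFrame(records, columns=["time_s", "membrane", "lipid_count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run(
    config: SimulationConfig | None = None,
    seed: object = 0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one cell cycle and return the sampled trajectory."""
    if config is None:
        config = default_config()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    state = initialize(config, rng)
    reactions = build_network(config)
    matrix = TransportMatrix.from_config(config)

    n_steps = config.n_steps
    sample_every = max(1, int(round(config.sample_interval / config.dt)))
    sample_steps = list(range(0, n_steps + 1, sample_every))
    if sample_steps[-1] != n_steps:
        sample_steps.append(n_steps)

    times = []
    counts: dict[str, list[int]] = {name: [] for name in MEMBRANE_NAMES}
    free_totals: list[int] = []
    acetyl: list[float] = []

    def record():
        times.append(state.t)
        for name in MEMBRANE_NAMES:
            counts[name].append(state.membranes[name].total())
        free_totals.append(state.total_free_lipids())
        acetyl.append(state.pools.consumed["acetyl_coa"])

    record()
    next_sample = 1
    for i in range(1, n_steps + 1):
        step(state, reactions, config, rng, transport_matrix=matrix)
        if next_sample < len(sample_steps) and i == sample_steps[next_sample]:
            record()
            next_sample += 1

    return Trajectory(
        times=np.asarray(times),
        membrane_counts={name: np.asarray(v) for name, v in counts.items()},
        free_lipid_totals=np.asarray(free_totals),
        acetyl_consumed=np.asarray(acetyl),
        final_state=state,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Summary of repeated runs: per-time-point mean/sd and final states."""

    times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    trajectories: list[Trajectory] = field(repr=False)

    @property
    def n_runs(self) -> int:
        return len(self.trajectories)

    @property
    def final_states(self) -> list[CellState]:
        return [t.final_state for t in self.trajectories]

    def final_mean(self, membrane: str) -> float:
        return float(self.mean[membrane][-1])

    def final_sd(self, membrane: str) -> float:
        return float(self.sd[membrane][-1])

    def final_total_mean(self) -> float:
        """Mean over runs of the final lipid count summed over all membranes."""
        totals = [
            sum(t.membrane_counts[name][-1] for name in MEMBRANE_NAMES)
            for t in self.trajectories
        ]
        return float(np.mean(totals))


def ensemble_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-run seed derived from a master seed and a counter."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(index),))


def run_ensemble(
    config: SimulationConfig | None = None,
    n_runs: int = 20,
    base_seed: int = 0,
    progress: bool = False,
) -> EnsembleResult:
    """Run an ensemble of independent simulations and summarize it."""
    if n_runs < 2:
        raise ValueError("an ensemble needs at least 2 runs")
    if config is None:
        config = default_config()
    trajectories = []
    for i in range(n_runs):
        rng = np.random.default_rng(ensemble_seed(base_seed, i))
        trajectories.append(run(config, seed=(base_seed, i), rng=rng))
        if progress:  # pragma: no cover
            print(f"run {i + 1}/{n_runs} done", flush=True)
    times = trajectories[0].times
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for name in MEMBRANE_NAMES:
        stack = np.stack([t.membrane_counts[name] for t in trajectories])
        mean[name] = stack.mean(axis=0)
        sd[name] = stack.std(axis=0, ddof=1)
    return EnsembleResult(times=times, mean=mean, sd=sd, trajectories=trajectories)
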