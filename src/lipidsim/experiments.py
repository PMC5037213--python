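"""Geometry helpers, composition statistics, perturbation experiments and
parameter sensitivities.

The two published-style perturbations are ergosterol-synthesis inhibition
(terbinafine: the lumped sterol reaction's n_max set to zero) and inositol
supplementation (an additional constant refill flux on the inositol pool).
Both are evaluated as perturbed-vs-control ensemble comparisons at the end of
the 120-min cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MEMBRANE_NAMES, POOL_NAMES, SimulationConfig, default_config
from .lipids import (
    ALL_FATTY_ACIDS,
    FattyAcid,
    LipidClass,
    MEMBRANE_CLASSES,
    PHOSPHOLIPID_CLASSES,
    chain_species_matrix,
)
from .state import CellState, Membrane
from .runner import EnsembleResult, run_ensemble

__all__ = [
    "sphere_area",
    "area_to_model_units",
    "knockout",
    "supplement",
    "fa_distribution",
    "es_pl_ratio",
    "agreement_r2",
    "composition_table",
    "ergosterol_knockout_experiment",
    "inositol_experiment",
    "sensitivity",
    "KnockoutResult",
    "SupplementResult",
]

#: membranes entering per-membrane composition comparisons (the droplet holds
#: only storage esters and is kept apart).
BILAYER_MEMBRANES = tuple(n for n in MEMBRANE_NAMES if n != "lipid_droplet")


# ---------------------------------------------------------------------------
# geometry and unit conversion
# ---------------------------------------------------------------------------

def sphere_area(volume_fl: float) -> float:
    """Surface area (um^2) of an ideal sphere of the given volume (fL).

    1 fL = 1 um^3, so A = (36 pi)^(1/3) V^(2/3).
    """
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    return (36.0 * math.pi) ** (1.0 / 3.0) * volume_fl ** (2.0 / 3.0)


def area_to_model_units(area_um2: float, config: SimulationConfig | None = None) -> float:
    """Convert a membrane area to lipid counts in model units.

    Uses the bilayer constant of 5x10^6 lipids per um^2 and the model scale
    of 10^4 molecules per count unit: 65.9 um^2 -> 32950 units.
    """
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    if config is None:
        config = default_config()
    return area_um2 * config.lipids_per_um2 / config.scale_factor


def model_units_to_area(count: float, config: SimulationConfig | None = None) -> float:
    """Inverse conversion: model-unit lipid count to membrane area (um^2)."""
    if config is None:
        config = default_config()
    return count * config.scale_factor / config.lipids_per_um2


# ---------------------------------------------------------------------------
# configuration perturbations
# ---------------------------------------------------------------------------

def knockout(
    config: SimulationConfig, reaction_name: str, factor: float = 0.0
) -> SimulationConfig:
    """Scale one reaction's n_max by `factor` (0 = full knockout)."""
    if reaction_name not in config.reactions:
        raise KeyError(
            f"unknown reaction '{reaction_name}'; valid names: "
            f"{sorted(config.reactions)}"
        )
    out = config.copy()
    out.reactions[reaction_name].n_max = int(round(
        config.reactions[reaction_name].n_max * factor))
    return out


def supplement(
    config: SimulationConfig, precursor: str, extra_rate: float
) -> SimulationConfig:
    """Add a constant supplementation flux to a precursor pool's refill."""
    if precursor not in POOL_NAMES:
        raise KeyError(
            f"unknown precursor '{precursor}'; valid names: {sorted(POOL_NAMES)}"
        )
    out = config.copy()
    out.pools.extra_refill[precursor] = (
        out.pools.extra_refill.get(precursor, 0.0) + extra_rate)
    return out


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------

_SPECIES_MATRICES = {cls: chain_species_matrix(cls) for cls in LipidClass}


def _chain_counts_of_state(state: CellState) -> np.ndarray:
    """Esterified chains per species over the whole lipidome (membranes,
    droplet and free lipid objects; the free fatty-acid pool is not
    esterified and is excluded)."""
    totals = np.zeros(len(ALL_FATTY_ACIDS), dtype=np.int64)
    for cls in LipidClass:
        mat = _SPECIES_MATRICES[cls]
        vec = state.free_lipids[cls]
        if vec.any():
            totals += vec @ mat
        for membrane in state.membranes.values():
            if cls in membrane.lipid_counts and membrane.lipid_counts[cls].any():
                totals += membrane.lipid_counts[cls] @ mat
    return totals


def fa_distribution(
    source: CellState | EnsembleResult,
) -> dict[FattyAcid, float]:
    """Fraction of each chain species among all esterified fatty acids.

    Accepts a single cell state or an ensemble (pooled over all final
    states).  Raises on an empty lipidome.
    """
    if isinstance(source, EnsembleResult):
        totals = sum((_chain_counts_of_state(s) for s in source.final_states),
                     np.zeros(len(ALL_FATTY_ACIDS), dtype=np.int64))
    else:
        totals = _chain_counts_of_state(source)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no esterified chains in the lipidome")
    return {fa: totals[i] / grand for i, fa in enumerate(ALL_FATTY_ACIDS)}


def es_pl_ratio(membrane: Membrane) -> float:
    """Ergosterol-to-phospholipid count ratio of one membrane."""
    counts = membrane.class_counts()
    phospholipids = sum(counts.get(cls, 0) for cls in PHOSPHOLIPID_CLASSES)
    if phospholipids == 0:
        raise ValueError(f"membrane {membrane.identity} holds no phospholipids")
    return counts.get(LipidClass.ES, 0) / phospholipids


def agreement_r2(simulated, target) -> float:
    """Coefficient of determination of a least-squares regression of simulated
    membrane/class fractions against their targets."""
    x = np.asarray(target, dtype=float).ravel()
    y = np.asarray(simulated, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equally sized fraction vectors")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def composition_table(source: CellState | EnsembleResult) -> pd.DataFrame:
    """Membrane x lipid-class fraction table (ensemble mean if given one).

    Export with ``df.to_csv(path, sep='\\t')``.
    """
    states = (source.final_states if isinstance(source, EnsembleResult)
              else [source])
    rows = {}
    for name in MEMBRANE_NAMES:
        fracs = []
        for state in states:
            membrane = state.membranes[name]
            total = membrane.total()
            if total == 0:
                continue
            counts = membrane.class_counts()
            fracs.append([counts.get(cls, 0) / total for cls in MEMBRANE_CLASSES])
        rows[name] = (np.mean(fracs, axis=0) if fracs
                      else np.zeros(len(MEMBRANE_CLASSES)))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[cls.value for cls in MEMBRANE_CLASSES]
    )


def _mean_class_fraction(
    ensemble: EnsembleResult, membrane: str, cls: LipidClass
) -> float:
    values = []
    for state in ensemble.final_states:
        total = state.membranes[membrane].total()
        if total:
            values.append(int(state.membranes[membrane].lipid_counts[cls].sum()) / total)
    return float(np.mean(values)) if values else 0.0


def _mean_class_count(
    ensemble: EnsembleResult, membrane: str, cls: LipidClass
) -> float:
    return float(np.mean([
        int(state.membranes[membrane].lipid_counts[cls].sum())
        for state in ensemble.final_states
    ]))


# ---------------------------------------------------------------------------
# perturbation experiments
# ---------------------------------------------------------------------------

@dataclass
class KnockoutResult:
    control: EnsembleResult
    perturbed: EnsembleResult
    es_fraction_control: dict[str, float]
    es_fraction_perturbed: dict[str, float]
    reduction_per_membrane: dict[str, float]  # relative reduction, percent
    mean_reduction_percent: float
    total_lipids_control: float
    total_lipids_perturbed: float


def ergosterol_knockout_experiment(
    config: SimulationConfig | None = None,
    n_runs: int = 20,
    base_seed: int = 0,
    control: EnsembleResult | None = None,
) -> KnockoutResult:
    """Terbinafine-style inhibition: ergosterol synthesis rate set to zero.

    Compares perturbed vs unperturbed ensembles at the end of the cycle.  The
    summary number is the relative decrease of each bilayer membrane's
    ergosterol fraction, averaged with the membranes weighted by their
    (control) ergosterol content, i.e. the reduction of the cell's membrane
    ergosterol pool; the droplet carries only steryl esters and is excluded.
    """
    if config is None:
        config = default_config()
    if control is None:
        control = run_ensemble(config, n_runs=n_runs, base_seed=base_seed)
    perturbed_cfg = knockout(config, "ergosterol_synthase", 0.0)
    perturbed = run_ensemble(perturbed_cfg, n_runs=n_runs, base_seed=base_seed + 1)

    frac_c = {m: _mean_class_fraction(control, m, LipidClass.ES)
              for m in BILAYER_MEMBRANES}
    frac_p = {m: _mean_class_fraction(perturbed, m, LipidClass.ES)
              for m in BILAYER_MEMBRANES}
    es_content = {m: _mean_class_count(control, m, LipidClass.ES)
                  for m in BILAYER_MEMBRANES}
    reduction = {
        m: 100.0 * (1.0 - frac_p[m] / frac_c[m]) if frac_c[m] > 0 else 0.0
        for m in BILAYER_MEMBRANES
    }
    weight_total = sum(es_content.values())
    mean_reduction = sum(
        es_content[m] * reduction[m] for m in BILAYER_MEMBRANES) / weight_total

    return KnockoutResult(
        control=control,
        perturbed=perturbed,
        es_fraction_control=frac_c,
        es_fraction_perturbed=frac_p,
        reduction_per_membrane=reduction,
        mean_reduction_percent=float(mean_reduction),
        total_lipids_control=control.final_total_mean(),
        total_lipids_perturbed=perturbed.final_total_mean(),
    )


@dataclass
class SupplementResult:
    control: EnsembleResult
    perturbed: EnsembleResult
    pi_fraction_control: dict[str, float]
    pi_fraction_perturbed: dict[str, float]
    pi_increase_points: dict[str, float]  # percentage points per membrane
    max_increase_membrane: str
    max_increase_points: float
    total_lipids_control: float
    total_lipids_perturbed: float


def inositol_experiment(
    config: SimulationConfig | None = None,
    n_runs: int = 20,
    base_seed: int = 0,
    extra_rate: float | None = None,
    control: EnsembleResult | None = None,
) -> SupplementResult:
    """Inositol feeding: an additional refill flux on the inositol pool.

    The default supplementation rate equals the baseline inositol production
    capacity (the glucose-6-phosphate refill), emulating replenishment from
    the medium alongside de novo synthesis.
    """
    if config is None:
        config = default_config()
    if extra_rate is None:
        extra_rate = config.pools.refill["glucose_6_p"]
    if control is None:
        control = run_ensemble(config, n_runs=n_runs, base_seed=base_seed)
    perturbed_cfg = supplement(config, "inositol", extra_rate)
    perturbed = run_ensemble(perturbed_cfg, n_runs=n_runs, base_seed=base_seed + 1)

    frac_c = {m: _mean_class_fraction(control, m, LipidClass.PI)
              for m in BILAYER_MEMBRANES}
    frac_p = {m: _mean_class_fraction(perturbed, m, LipidClass.PI)
              for m in BILAYER_MEMBRANES}
    delta = {m: 100.0 * (frac_p[m] - frac_c[m]) for m in BILAYER_MEMBRANES}
    best = max(delta, key=delta.get)

    return SupplementResult(
        control=control,
        perturbed=perturbed,
        pi_fraction_control=frac_c,
        pi_fraction_perturbed=frac_p,
        pi_increase_points=delta,
        max_increase_membrane=best,
        max_increase_points=delta[best],
        total_lipids_control=control.final_total_mean(),
        total_lipids_perturbed=perturbed.final_total_mean(),
    )


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity(
    config: SimulationConfig | None = None,
    n_runs: int = 4,
    delta: int = 1,
    reactions: list[str] | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Finite-difference sensitivities of final membrane sizes to n_max.

    s(i, j) = 100 * (mean final size of membrane i with n_max_j + delta
    - baseline mean) / (baseline mean * delta), from ensemble means.
    Returns a membranes x reactions table in percent per parameter unit.
    """
    if config is None:
        config = default_config()
    if n_runs < 2:
        raise ValueError("sensitivities require an ensemble (n_runs >= 2)")
    if reactions is None:
        reactions = list(config.reactions)
    baseline = run_ensemble(config, n_runs=n_runs, base_seed=base_seed)
    base_final = {m: baseline.final_mean(m) for m in MEMBRANE_NAMES}
    table = {}
    for j, name in enumerate(reactions):
        perturbed_cfg = config.copy()
        perturbed_cfg.reactions[name].n_max += int(delta)
        perturbed = run_ensemble(perturbed_cfg, n_runs=n_runs, base_seed=base_seed)
        table[name] = [
            100.0 * (perturbed.final_mean(m) - base_final[m])
            / (base_final[m] * delta) if base_final[m] else float("nan")
            for m in MEMBRANE_NAMES
        ]
    return pd.DataFrame(table, index=list(MEMBRANE_NAMES))
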