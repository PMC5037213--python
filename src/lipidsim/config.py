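"""Simulation configuration: kinetic parameters, membrane targets, schedules.

Everything the simulator does is driven by a `SimulationConfig`: time stepping
and cell-cycle phase boundaries, precursor refill rates, per-reaction kinetic
parameters (``n_max``, per-substrate ``km``), membrane initial sizes /
composition targets / transport size weights, and droplet flux magnitudes.

All lipid and precursor counts are expressed in *model units* of 10^4 real
molecules; Km values use the same unit.  The shipped defaults encode the
calibrated reference parameterization of the study conditions: a 50 fL cell in
early G1 that doubles its membrane surface over one 120-min cell cycle (1 s
steps), with membrane sizes and composition anchors taken from the published
organelle data (plasma membrane ES/PL ratio 0.94, cardiolipin confined to the
mitochondria, ergosterol-rich plasma membrane, fatty-acid pool approaching
50% C18:1 / 30% C16:1 / 9% C16:0 / 11% C18:0).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from .lipids import LipidClass, MEMBRANE_CLASSES

__all__ = [
    "ReactionParameters",
    "PoolConfig",
    "MembraneConfig",
    "SimulationConfig",
    "ConfigurationError",
    "default_config",
    "load_config",
    "dump_config",
]

#: Names of the nine membrane compartments.
MEMBRANE_NAMES: tuple[str, ...] = (
    "plasma",
    "secretory_vesicles",
    "vacuole",
    "nucleus",
    "peroxisome",
    "light_microsomes",
    "inner_mito",
    "outer_mito",
    "lipid_droplet",
)

#: Precursor pool names.
POOL_NAMES: tuple[str, ...] = (
    "pyruvate",
    "acetyl_coa",
    "dhap",
    "glycerol_3_p",
    "ctp",
    "serine",
    "glucose_6_p",
    "inositol",
    "ceramide",
)

#: Bilayer conversion constant: lipids per um^2 of membrane (both leaflets).
LIPIDS_PER_UM2 = 5.0e6
#: Model-unit scale: one count unit represents this many real molecules.
SCALE_FACTOR = 1.0e4


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural constraint."""


@dataclass
class ReactionParameters:
    """Kinetic parameters of one reaction rule.

    n_max: maximum number of executions per 1 s time step (stochastic vmax
    analogue). km: Michaelis constant per substrate, in model count units.
    fa_weights: categorical weights over (C16:0, C16:1, C18:0, C18:1) used when
    the rule attaches a chain.  phases: cell-cycle phases in which the rule is
    active (None = always).
    """

    n_max: int
    km: dict[str, float] = field(default_factory=dict)
    fa_weights: tuple[float, float, float, float] | None = None
    phases: tuple[str, ...] | None = None

    def validate(self, name: str = "?") -> None:
        if self.n_max < 0:
            raise ConfigurationError(f"{name}: n_max must be >= 0")
        for sub, km in self.km.items():
            if km <= 0:
                raise ConfigurationError(f"{name}: Km({sub}) must be > 0")
        if self.fa_weights is not None:
            if len(self.fa_weights) != 4 or any(w < 0 for w in self.fa_weights):
                raise ConfigurationError(f"{name}: fa_weights must be 4 non-negative values")
            if abs(sum(self.fa_weights) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: fa_weights must sum to 1")


@dataclass
class PoolConfig:
    """Initial precursor levels and per-step refill rates (model units)."""

    initial: dict[str, float]
    refill: dict[str, float]
    #: Supplementation fluxes added on top of `refill` (used by the inositol
    #: feeding experiment); empty by default.
    extra_refill: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for table, label in ((self.initial, "initial"), (self.refill, "refill"),
                             (self.extra_refill, "extra_refill")):
            for pool, value in table.items():
                if pool not in POOL_NAMES:
                    raise ConfigurationError(f"unknown precursor pool '{pool}'")
                if value < 0:
                    raise ConfigurationError(f"{label}[{pool}] must be >= 0")


@dataclass
class MembraneConfig:
    """Initial size, transport size weight and composition target of a membrane."""

    initial_count: float
    size_weight: float
    composition_target: dict[str, float]

    def validate(self, name: str = "?") -> None:
        if self.initial_count < 0 or self.size_weight < 0:
            raise ConfigurationError(f"{name}: counts and weights must be >= 0")
        total = sum(self.composition_target.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{name}: composition_target sums to {total!r}, expected 1"
            )
        valid = {c.value for c in MEMBRANE_CLASSES}
        for cls, frac in self.composition_target.items():
            if cls not in valid:
                raise ConfigurationError(f"{name}: '{cls}' is not a membrane lipid class")
            if frac < 0:
                raise ConfigurationError(f"{name}: negative target fraction for {cls}")


@dataclass
class SimulationConfig:
    # -- time stepping and cell cycle (seconds) --
    dt: float = 1.0
    horizon: float = 7200.0
    g1_end: float = 1800.0
    s_end: float = 3600.0
    g2_end: float = 6300.0
    # -- geometry / unit conversions --
    scale_factor: float = SCALE_FACTOR
    lipids_per_um2: float = LIPIDS_PER_UM2
    initial_volume_fl: float = 50.0
    final_mother_volume_fl: float = 62.5
    final_bud_volume_fl: float = 37.5
    # -- transport and lipid droplet --
    transport_fraction: float = 0.1
    #: G1-phase droplet influx, model units per step for each of TAG and SE.
    droplet_influx: float = 0.5
    #: post-G1 droplet efflux, model units per step for each of TAG and SE.
    droplet_efflux: float = 0.04
    # -- initialization --
    init_noise: float = 0.05
    free_pool_fraction: float = 0.05
    initial_free_fatty_acids: float = 60.0
    #: starting free counts for the non-membrane intermediates, so the
    #: synthesis chain does not start from an empty pipeline.
    initial_free_intermediates: dict[str, float] = field(
        default_factory=lambda: {"lysoPA": 40.0, "CDP_DG": 45.0})
    # -- recording --
    sample_interval: float = 10.0
    # -- components --
    membranes: dict[str, MembraneConfig] = field(default_factory=dict)
    pools: PoolConfig = None  # type: ignore[assignment]
    reactions: dict[str, ReactionParameters] = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))

    def validate(self) -> None:
        if abs(self.horizon / self.dt - round(self.horizon / self.dt)) > 1e-9:
            raise ConfigurationError("horizon must be an integer number of steps")
        if not (0.0 <= self.transport_fraction <= 1.0):
            raise ConfigurationError("transport_fraction must lie in [0, 1]")
        if self.horizon > 0:
            if not (0.0 < self.g1_end < self.horizon):
                raise ConfigurationError("g1_end must lie inside the horizon")
            if not (self.g1_end <= self.s_end <= self.g2_end <= self.horizon):
                raise ConfigurationError("phase boundaries must be ordered")
        if self.init_noise < 0 or self.droplet_influx < 0 or self.droplet_efflux < 0:
            raise ConfigurationError("noise and droplet fluxes must be >= 0")
        for name in MEMBRANE_NAMES:
            if name not in self.membranes:
                raise ConfigurationError(f"missing membrane '{name}'")
        for name, mem in self.membranes.items():
            mem.validate(name)
        self.pools.validate()
        for name, params in self.reactions.items():
            params.validate(name)

    def copy(self) -> "SimulationConfig":
        return copy.deepcopy(self)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for params in d["reactions"].values():
            if params["fa_weights"] is not None:
                params["fa_weights"] = list(params["fa_weights"])
            if params["phases"] is not None:
                params["phases"] = list(params["phases"])
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        data = copy.deepcopy(dict(data))
        membranes = {
            name: MembraneConfig(**m) for name, m in data.pop("membranes", {}).items()
        }
        pools = PoolConfig(**data.pop("pools"))
        reactions = {}
        for name, p in data.pop("reactions", {}).items():
            if p.get("fa_weights") is not None:
                p["fa_weights"] = tuple(p["fa_weights"])
            if p.get("phases") is not None:
                p["phases"] = tuple(p["phases"])
            reactions[name] = ReactionParameters(**p)
        cfg = cls(membranes=membranes, pools=pools, reactions=reactions, **data)
        cfg.validate()
        return cfg


def load_config(path) -> SimulationConfig:
    """Load a configuration from YAML; missing keys fall back to defaults."""
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    base = default_config().to_dict()
    _deep_merge(base, overrides)
    return SimulationConfig.from_dict(base)


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _deep_merge(base: dict, overrides: Mapping) -> None:
    for key, value in overrides.items():
        if key in base and isinstance(base[key], dict) and isinstance(value, Mapping):
            _deep_merge(base[key], value)
        else:
            base[key] = value


# ---------------------------------------------------------------------------
# Default parameterization
# ---------------------------------------------------------------------------

#: Synthesis weights over (C16:0, C16:1, C18:0, C18:1): the target distribution
#: of the esterified fatty-acid pool; rare species are lumped into C18:0.
DEFAULT_FA_WEIGHTS: tuple[float, float, float, float] = (0.09, 0.30, 0.11, 0.50)

# Membrane initial sizes in model units (10^4 lipids): plasma membrane from the
# spherical 50 fL cell (65.9 um^2), nucleus / vacuole / outer mitochondria from
# measured organelle areas (12 / 5 / 5 um^2), the rest physiological estimates.
# size_weight is the expected net growth over the cycle, so that transport
# weights (size x composition) apportion production according to demand.
_MEMBRANE_TABLE: dict[str, tuple[float, float]] = {
    # name: (initial count, final target count)
    "plasma": (32950.0, 60195.0),
    "secretory_vesicles": (500.0, 975.0),
    "vacuole": (2500.0, 10812.0),
    "nucleus": (6000.0, 10756.0),
    "peroxisome": (500.0, 858.0),
    "light_microsomes": (500.0, 817.0),
    "inner_mito": (5000.0, 6828.0),
    "outer_mito": (2500.0, 3363.0),
    "lipid_droplet": (1000.0, 1799.0),
}

_COMPOSITION_TARGETS: dict[str, dict[str, float]] = {
    # Ergosterol-rich plasma membrane; ES/PL = 0.4136/0.44 = 0.94.
    "plasma": {"PA": 0.015, "PS": 0.16, "PE": 0.095, "PC": 0.10, "PI": 0.08,
               "CL": 0.0, "DAG": 0.02, "TAG": 0.015, "ES": 0.423,
               "SE": 0.025, "SL": 0.067},
    "secretory_vesicles": {"PA": 0.02, "PS": 0.12, "PE": 0.12, "PC": 0.20,
                           "PI": 0.10, "CL": 0.0, "DAG": 0.03, "TAG": 0.02,
                           "ES": 0.30, "SE": 0.03, "SL": 0.06},
    # PI-rich vacuolar membrane.
    "vacuole": {"PA": 0.02, "PS": 0.04, "PE": 0.17, "PC": 0.40, "PI": 0.26,
                "CL": 0.01, "DAG": 0.02, "TAG": 0.02, "ES": 0.03, "SE": 0.01,
                "SL": 0.02},
    "nucleus": {"PA": 0.03, "PS": 0.06, "PE": 0.24, "PC": 0.41, "PI": 0.16,
                "CL": 0.01, "DAG": 0.02, "TAG": 0.015, "ES": 0.04,
                "SE": 0.005, "SL": 0.01},
    "peroxisome": {"PA": 0.03, "PS": 0.05, "PE": 0.22, "PC": 0.44, "PI": 0.14,
                   "CL": 0.03, "DAG": 0.02, "TAG": 0.015, "ES": 0.04,
                   "SE": 0.005, "SL": 0.01},
    "light_microsomes": {"PA": 0.03, "PS": 0.06, "PE": 0.25, "PC": 0.42,
                         "PI": 0.15, "CL": 0.0, "DAG": 0.02, "TAG": 0.015,
                         "ES": 0.04, "SE": 0.005, "SL": 0.01},
    # Cardiolipin enriched in the inner mitochondrial membrane.
    "inner_mito": {"PA": 0.02, "PS": 0.04, "PE": 0.24, "PC": 0.38, "PI": 0.14,
                   "CL": 0.16, "DAG": 0.005, "TAG": 0.0, "ES": 0.01,
                   "SE": 0.0, "SL": 0.005},
    "outer_mito": {"PA": 0.03, "PS": 0.04, "PE": 0.23, "PC": 0.43, "PI": 0.14,
                   "CL": 0.06, "DAG": 0.02, "TAG": 0.01, "ES": 0.03,
                   "SE": 0.0, "SL": 0.01},
    # Neutral-lipid store: TAG and steryl esters, 50:50.  Fed by the
    # phase-dependent droplet fluxes, not by the transport stage.
    "lipid_droplet": {"TAG": 0.5, "SE": 0.5},
}

_DEFAULT_POOLS = {
    "initial": {
        "pyruvate": 120.0, "acetyl_coa": 190.0, "dhap": 260.0,
        "glycerol_3_p": 260.0, "ctp": 255.0, "serine": 280.0,
        "glucose_6_p": 100.0, "inositol": 190.0, "ceramide": 40.0,
    },
    # Per-step replenishment from central carbon metabolism; these rates set
    # the sustainable pathway fluxes.
    "refill": {
        "pyruvate": 107.0, "acetyl_coa": 0.0, "dhap": 2.0,
        "glycerol_3_p": 2.06, "ctp": 4.17, "serine": 2.86,
        "glucose_6_p": 1.07, "inositol": 0.0, "ceramide": 0.29,
    },
}

# Km values are expressed in model units and were calibrated (together with
# n_max and the refill rates) so that pathway fluxes match the membrane demand
# implied by the size/composition targets.  The two anchored maxima are the
# acetyl-CoA synthase (650) and the PC synthase (5).
_DEFAULT_REACTIONS: dict[str, dict] = {
    "acetyl_coa_synthase": dict(n_max=650, km={"pyruvate": 500.0}),
    "inositol_synthase": dict(n_max=3, km={"glucose_6_p": 150.0}),
    "fatty_acid_synthase": dict(n_max=17, km={"acetyl_coa": 200.0},
                                fa_weights=DEFAULT_FA_WEIGHTS),
    "lyso_pa_synthase_g3p": dict(n_max=6, km={"glycerol_3_p": 100.0,
                                              "fatty_acid": 30.0}),
    "lyso_pa_synthase_dhap": dict(n_max=6, km={"dhap": 100.0,
                                               "fatty_acid": 30.0}),
    "pa_synthase": dict(n_max=12, km={"lysoPA": 15.0,
                                      "unsaturated_fatty_acid": 12.0}),
    "cdp_dg_synthase": dict(n_max=9, km={"PA": 0.5, "ctp": 150.0}),
    "ps_synthase": dict(n_max=10, km={"CDP_DG": 30.0, "serine": 50.0}),
    "pi_synthase": dict(n_max=5, km={"CDP_DG": 24.0, "inositol": 60.0}),
    "cl_synthase": dict(n_max=1, km={"CDP_DG": 60.0, "glycerol_3_p": 100.0}),
    "ps_decarboxylase": dict(n_max=5, km={"PS": 10.0}),
    "pc_synthase": dict(n_max=5, km={"PE": 24.0}),
    "pa_phosphatase": dict(n_max=1, km={"PA": 10.0}),
    "dag_kinase": dict(n_max=1, km={"DAG": 10.0, "ctp": 150.0}),
    "tag_synthase": dict(n_max=2, km={"DAG": 5.0, "fatty_acid": 30.0}),
    "tag_lipase": dict(n_max=1, km={"TAG": 20.0}, phases=("S", "G2", "M")),
    "ergosterol_synthase": dict(n_max=4, km={"acetyl_coa": 250.0}),
    "se_synthase": dict(n_max=1, km={"ES": 60.0, "fatty_acid": 30.0}),
    "se_hydrolase": dict(n_max=1, km={"SE": 20.0}, phases=("S", "G2", "M")),
    "sphingolipid_synthase": dict(n_max=2, km={"ceramide": 30.0, "PI": 15.0}),
}


def default_config() -> SimulationConfig:
    """The calibrated reference configuration for one 120-min cell cycle."""
    membranes = {
        name: MembraneConfig(
            initial_count=initial,
            size_weight=(final - initial) if name != "lipid_droplet" else 0.0,
            composition_target=dict(_COMPOSITION_TARGETS[name]),
        )
        for name, (initial, final) in _MEMBRANE_TABLE.items()
    }
    pools = PoolConfig(
        initial=dict(_DEFAULT_POOLS["initial"]),
        refill=dict(_DEFAULT_POOLS["refill"]),
    )
    reactions = {
        name: ReactionParameters(
            n_max=spec["n_max"],
            km=dict(spec["km"]),
            fa_weights=spec.get("fa_weights"),
            phases=spec.get("phases"),
        )
        for name, spec in _DEFAULT_REACTIONS.items()
    }
    cfg = SimulationConfig(membranes=membranes, pools=pools, reactions=reactions)
    cfg.validate()
    return cfg
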