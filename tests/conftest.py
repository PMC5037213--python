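import numpy as np
import pytest

import lipidsim as L
from lipidsim.config import default_config
from lipidsim.state import CellState, Membrane, PrecursorPool, empty_free_pools
from lipidsim.lipids import MEMBRANE_CLASSES


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cfg():
    return default_config()


def make_empty_state(rng=None, pools=None):
    """A bare cell state with empty pools, for targeted reaction tests."""
    counts = {name: 0.0 for name in L.config.POOL_NAMES} if not pools else dict(pools)
    for name in L.config.POOL_NAMES:
        counts.setdefault(name, 0.0)
    membranes = {
        name: Membrane(identity=name, composition_target={}, size_weight=0.0)
        for name in L.config.MEMBRANE_NAMES
    }
    return CellState(
        t=0.0,
        phase="G1",
        pools=PrecursorPool(counts=counts, refill_rates={}, extra_refill={}),
        free_fatty_acids=np.zeros(4, dtype=np.int64),
        free_lipids=empty_free_pools(),
        membranes=membranes,
        rng=rng if rng is not None else np.random.default_rng(0),
    )


@pytest.fixture
def empty_state(rng):
    return make_empty_state(rng)


# ---------------------------------------------------------------------------
# shared heavy ensembles for the acceptance checks (session scope so the
# control ensemble is reused by several comparisons)
# ---------------------------------------------------------------------------

ACCEPT_RUNS = 20
ACCEPT_SEED = 1


@pytest.fixture(scope="session")
def control_ensemble():
    return L.run_ensemble(default_config(), n_runs=ACCEPT_RUNS, base_seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def knockout_result(control_ensemble):
    return L.ergosterol_knockout_experiment(
        default_config(), n_runs=ACCEPT_RUNS, base_seed=ACCEPT_SEED,
        control=control_ensemble)


@pytest.fixture(scope="session")
def supplement_result(control_ensemble):
    return L.inositol_experiment(
        default_config(), n_runs=ACCEPT_RUNS, base_seed=ACCEPT_SEED,
        control=control_ensemble)
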