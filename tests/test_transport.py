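import numpy as np
import pytest

from lipidsim.config import default_config
from lipidsim.lipids import LipidClass, MEMBRANE_CLASSES
from lipidsim.transport import (
    BILAYER_MEMBRANES,
    TransportMatrix,
    distribute,
    droplet_flux,
    phase_of,
)

from conftest import make_empty_state


class TestTransportMatrix:
    def test_rows_normalized_per_class(self, cfg):
        matrix = TransportMatrix.from_config(cfg)
        for cls in MEMBRANE_CLASSES:
            row = matrix.weights[cls]
            if row is not None:
                assert row.sum() == pytest.approx(1.0)
                assert np.all(row >= 0)

    def test_zero_target_membranes_get_zero_weight(self, cfg):
        """Cardiolipin stays out of membranes whose CL target is zero."""
        matrix = TransportMatrix.from_config(cfg)
        row = matrix.weights[LipidClass.CL]
        plasma_idx = matrix.membranes.index("plasma")
        inner_idx = matrix.membranes.index("inner_mito")
        assert row[plasma_idx] == 0.0
        assert row[inner_idx] > 0.5  # CL is mitochondria-bound


class TestDistribute:
    def test_ten_percent_of_the_pool_moves(self, cfg, rng):
        state = make_empty_state(rng)
        state.free_lipids[LipidClass.PA][0] = 100
        matrix = TransportMatrix.from_config(cfg)
        distribute(state, matrix, 0.1, rng)
        assert state.free_lipids[LipidClass.PA].sum() == 90
        moved = sum(state.membranes[m].lipid_counts[LipidClass.PA].sum()
                    for m in BILAYER_MEMBRANES)
        assert moved == 10

    def test_zero_fraction_is_noop(self, cfg, rng):
        state = make_empty_state(rng)
        state.free_lipids[LipidClass.PC][3] = 55
        distribute(state, TransportMatrix.from_config(cfg), 0.0, rng)
        assert state.free_lipids[LipidClass.PC][3] == 55

    def test_split_follows_weights(self, rng):
        """1e4 objects split over two membranes with weights 0.7/0.3."""
        state = make_empty_state(rng)
        n = 10_000
        state.free_lipids[LipidClass.PC][0] = n
        row = np.zeros(len(BILAYER_MEMBRANES))
        row[0], row[1] = 0.7, 0.3
        matrix = TransportMatrix(
            membranes=BILAYER_MEMBRANES,
            weights={cls: (row if cls is LipidClass.PC else None)
                     for cls in MEMBRANE_CLASSES},
        )
        distribute(state, matrix, 1.0, rng)
        first = state.membranes[BILAYER_MEMBRANES[0]].lipid_counts[LipidClass.PC].sum()
        sigma = np.sqrt(n * 0.7 * 0.3)
        assert abs(first - 0.7 * n) < 3 * sigma

    def test_conservation_per_class(self, cfg, rng):
        state = make_empty_state(rng)
        totals = {}
        for i, cls in enumerate(MEMBRANE_CLASSES):
            state.free_lipids[cls][0] = 40 + i
            totals[cls] = 40 + i
        distribute(state, TransportMatrix.from_config(cfg), 0.25, rng)
        for cls in MEMBRANE_CLASSES:
            in_membranes = sum(
                state.membranes[m].lipid_counts[cls].sum()
                for m in BILAYER_MEMBRANES)
            assert state.free_lipids[cls].sum() + in_membranes == totals[cls]


class TestDropletFlux:
    def test_g1_influx_is_a_5050_mix(self, cfg, rng):
        state = make_empty_state(rng)
        state.free_lipids[LipidClass.TAG][0] = 10_000
        state.free_lipids[LipidClass.SE][0] = 10_000
        cfg.droplet_influx = 2.0
        for _ in range(500):
            droplet_flux(state, cfg, rng)
        droplet = state.membranes["lipid_droplet"]
        tag = droplet.lipid_counts[LipidClass.TAG].sum()
        se = droplet.lipid_counts[LipidClass.SE].sum()
        assert tag == 1000 and se == 1000

    def test_influx_limited_by_availability(self, cfg, rng):
        state = make_empty_state(rng)
        state.free_lipids[LipidClass.TAG][0] = 3
        cfg.droplet_influx = 10.0
        droplet_flux(state, cfg, rng)
        droplet = state.membranes["lipid_droplet"]
        assert droplet.lipid_counts[LipidClass.TAG].sum() == 3
        assert state.free_lipids[LipidClass.TAG].sum() == 0

    def test_efflux_empties_then_noops(self, cfg, rng):
        state = make_empty_state(rng)
        state.phase = "S"
        droplet = state.membranes["lipid_droplet"]
        droplet.lipid_counts[LipidClass.SE][0] = 5
        cfg.droplet_efflux = 100.0
        droplet_flux(state, cfg, rng)
        assert droplet.lipid_counts[LipidClass.SE].sum() == 0
        assert state.free_lipids[LipidClass.SE].sum() == 5
        droplet_flux(state, cfg, rng)  # empty droplet: silent no-op
        assert state.free_lipids[LipidClass.SE].sum() == 5


class TestPhaseClock:
    @pytest.mark.parametrize("t,phase", [
        (0.0, "G1"),
        (1799.0, "G1"),
        (1800.0, "S"),
        (3600.0, "G2"),
        (6300.0, "M"),
        (7200.0, "M"),
    ])
    def test_boundaries(self, cfg, t, phase):
        assert phase_of(t, cfg) == phase

    @pytest.mark.parametrize("t", [-1.0, 7201.0])
    def test_out_of_range(self, cfg, t):
        with pytest.raises(ValueError):
            phase_of(t, cfg)
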