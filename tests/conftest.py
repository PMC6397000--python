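"""Shared synthetic fixtures: one small simulated session reused by the
rate-map, field-detection, metric and theta tests."""

import warnings

import numpy as np
import pytest

from placecode import BinGrid, simulate_trajectory
from placecode.ratemaps import firing_rate_map, rate_maps_by_direction
from placecode.placefields import detect_place_fields
from placecode.simulate import (LfpSpec, PlaceCellSpec, simulate_lfp,
                                simulate_place_cell)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def grid():
    return BinGrid()


@pytest.fixture(scope="session")
def traj30():
    return simulate_trajectory(30, seed=2)


@pytest.fixture(scope="session")
def lfp_phase(traj30):
    lfp, phase = simulate_lfp(traj30, LfpSpec(), seed=3)
    return lfp, phase


@pytest.fixture(scope="session")
def place_spec():
    return PlaceCellSpec(center_forth=100.0, center_back=100.0,
                         width_sigma=8.0, peak_rate=8.0, baseline_rate=0.5,
                         precession_slope=-2.0, theta_mod_depth=0.6)


@pytest.fixture(scope="session")
def place_train(traj30, lfp_phase, place_spec):
    lfp, phase = lfp_phase
    return simulate_place_cell(traj30, place_spec, seed=4,
                               lfp_phase=(lfp.t, phase), cell_id=0)


@pytest.fixture(scope="session")
def place_maps(traj30, place_train, grid):
    return rate_maps_by_direction(traj30, place_train, grid)


@pytest.fixture(scope="session")
def detected_fields(place_maps):
    return {d: detect_place_fields(rm, n_boot=500, seed=5)
            for d, rm in place_maps.items()}


@pytest.fixture(scope="session")
def tiled_ensemble(grid):
    """10 bidirectional place cells tiling the track, 12 trials."""
    rng = np.random.default_rng(7)
    traj = simulate_trajectory(12, seed=rng)
    lfp, phase = simulate_lfp(traj, LfpSpec(), seed=rng)
    trains, maps = [], {}
    for i, c in enumerate(np.linspace(35, 165, 10)):
        spec = PlaceCellSpec(center_forth=float(c), center_back=float(c),
                             width_sigma=8.0, peak_rate=8.0,
                             baseline_rate=0.5)
        st = simulate_place_cell(traj, spec, rng, (lfp.t, phase), cell_id=i)
        trains.append(st)
        maps[i] = rate_maps_by_direction(traj, st, grid)
    return traj, trains, maps
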