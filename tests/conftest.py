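import numpy as np
import pandas as pd
import pytest

from smdyn.params import SimulationParams
from smdyn.simulate import simulate_trajectories
from smdyn.trajectories import TrajectorySet


@pytest.fixture(scope="session")
def single_state_traj():
    """One free state, D = 0.25 μm²/s, no localization noise."""
    p = SimulationParams(
        D=(0.25,),
        rate_matrix=np.zeros((1, 1)),
        confinement_side=(None,),
        loc_sigma=0.0,
        n_particles=150,
        track_lifetime_mean=30,
        n_frames=60,
        seed=42,
    )
    traj, gt = simulate_trajectories(p)
    return p, traj, gt


@pytest.fixture(scope="session")
def two_state_traj():
    """Well-separated two-state simulation with slow switching."""
    Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
    p = SimulationParams(
        D=(0.01, 0.3),
        rate_matrix=Q,
        confinement_side=(None, None),
        oligomer_dist=np.array([[0.5, 0.5], [0.5, 0.5]]),
        loc_sigma=0.0,
        n_particles=500,
        track_lifetime_mean=25,
        n_frames=100,
        seed=7,
    )
    traj, gt = simulate_trajectories(p)
    return p, traj, gt


def make_traj(rows, dt=0.0305, cell_area=None, columns=None):
    """Hand-built trajectory set from (cell, particle, frame, x, y[, ...]) rows."""
    cols = columns or ["cell_id", "particle_id", "frame", "x_um", "y_um"]
    return TrajectorySet(
        pd.DataFrame(rows, columns=cols), dt=dt, cell_area_um2=cell_area
    )
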