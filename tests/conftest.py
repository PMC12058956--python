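import warnings

import numpy as np
import pytest

from shoalnet.trajectory_io import TrajectorySet, MissingFramesWarning
from shoalnet.collective_metrics import behavior_table
from shoalnet.synthetic_data import SimulationConfig, simulate_dataset


def make_trajectory(
    positions,
    fps=1.0,
    frame_index=None,
    fish_ids=None,
    body_lengths=None,
    group_id="g",
    trial=1,
    arena_diameter=120.0,
):
    """Build a TrajectorySet from an (F, 8, 2) array of coordinates."""
    positions = np.asarray(positions, dtype=float)
    if frame_index is None:
        frame_index = np.arange(len(positions))
    if fish_ids is None:
        fish_ids = [f"f{i}" for i in range(1, 9)]
    if body_lengths is None:
        body_lengths = {f: 4.0 for f in fish_ids}
    return TrajectorySet(
        group_id=group_id,
        trial=trial,
        fps=fps,
        fish_ids=list(fish_ids),
        positions=positions,
        frame_index=frame_index,
        body_lengths=body_lengths,
        arena_diameter=arena_diameter,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Full 30-group study design at reduced temporal resolution (5 fps,
    2-minute trials) so the whole bundle simulates in well under a second."""
    cfg = SimulationConfig(fps=5.0, trial_duration_s=120.0, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_behavior(small_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingFramesWarning)
        return behavior_table(small_sim.trajectories, small_sim.meta)
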