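import numpy as np
import pandas as pd
import pytest

from shoalnoise import (
    DisruptionSpec,
    SimulationConfig,
    TrajectoryDataset,
    TrialDesign,
    regular_octagon,
    simulate_trial,
)


@pytest.fixture(scope="session")
def arena():
    return regular_octagon(105.0)


def make_dataset(
    positions: np.ndarray,
    fps: float = 10.0,
    half_boundary=None,
    treatment: str = "ambient",
    trial_id: str = "test",
    arena=None,
) -> TrajectoryDataset:
    """Build a dataset from a (n_frames, n_fish, 2) array of cm positions."""
    positions = np.asarray(positions, dtype=float)
    return TrajectoryDataset(
        trial_id=trial_id,
        positions=positions,
        frames=np.arange(positions.shape[0]),
        fish_ids=np.arange(positions.shape[1]),
        fps=fps,
        arena=arena if arena is not None else regular_octagon(105.0),
        half_boundary=half_boundary,
        treatment=treatment,
    )


@pytest.fixture
def square_walk():
    """Four fish at unit-square corners drifting along +x at 1 cm/frame."""
    T = 20
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    pos = corners[None, :, :] + np.arange(T)[:, None, None] * np.array([1.0, 0.0])
    pos -= pos.mean(axis=(0, 1))
    return make_dataset(pos)


@pytest.fixture(scope="session")
def sim_trial():
    """One simulated trial at desk scale (identity disruption)."""
    return simulate_trial(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def disrupted_trial():
    cfg = SimulationConfig(seed=43, disruption=DisruptionSpec(0.6, 0.6, 0.7, 1.5))
    return simulate_trial(cfg, treatment="pile_driving")


def write_csv(tmp_path, df: pd.DataFrame, name: str = "traj.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def basic_design():
    return TrialDesign(
        trial_id="t1",
        treatment="ambient",
        fps=10.0,
        half_boundary=5,
        n_fish=4,
        cm_per_pixel=1.0,
    )
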