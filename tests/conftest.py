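import numpy as np
import pytest

from claysoup.bondgraph_species import ThresholdTable
from claysoup.trajectory_io import Frame, SimulationCell, Trajectory


@pytest.fixture
def cell():
    return SimulationCell(10.30, 17.96, 7.41)


@pytest.fixture
def cube_cell():
    return SimulationCell(20.0, 20.0, 20.0)


@pytest.fixture
def thresholds():
    return ThresholdTable()


def make_trajectory(elements, positions_per_frame, cell, spacing=4.0):
    """Trajectory from a list of (N, 3) arrays."""
    frames = [
        Frame(index=i, time=i * spacing, positions=np.asarray(p, dtype=float))
        for i, p in enumerate(positions_per_frame)
    ]
    return Trajectory(elements=list(elements), frames=frames, cell=cell)


@pytest.fixture
def random_trajectory(cube_cell):
    """Small random-walk trajectory helper, deterministic per seed."""

    def _make(n_atoms=10, n_frames=20, seed=0, elements=None, step=0.1):
        rng = np.random.default_rng(seed)
        if elements is None:
            elements = list(rng.choice(["C", "N", "O", "H"], size=n_atoms))
        pos = rng.uniform(0, 20.0, (n_atoms, 3))
        frames = []
        for i in range(n_frames):
            pos = pos + rng.normal(0, step, (n_atoms, 3))
            frames.append(Frame(index=i, time=i * 4.0, positions=pos.copy()))
        return Trajectory(elements=elements, frames=frames, cell=cube_cell)

    return _make
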