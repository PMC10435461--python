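import numpy as np
import pytest

from cypdyn.synthetic import (
    LangevinParams,
    ToyComplexSpec,
    build_toy_complex,
    simulate_toy_trajectory,
)


@pytest.fixture(scope="session")
def toy_complex():
    """Default 20-residue bead complex (topology, reference coords)."""
    return build_toy_complex(ToyComplexSpec(seed=123))


@pytest.fixture(scope="session")
def toy_trajectory(toy_complex):
    """Short 3-state metastable trajectory with ground-truth labels."""
    topology, reference = toy_complex
    rng = np.random.default_rng(99)
    anchors = [reference]
    mobile = np.concatenate(
        [topology.region_indices("beta"), topology.region_indices("bb_loop")]
    )
    for direction in ([3.0, 0, 0], [0, 3.0, 0]):
        a = reference.copy()
        a[mobile] += np.asarray(direction, dtype=float)
        anchors.append(a)
    traj, labels = simulate_toy_trajectory(
        topology,
        anchors,
        weights=(0.5, 0.3, 0.2),
        params=LangevinParams(dt=0.1, friction=1.0, n_steps=600, seed=42),
        switch_prob=0.05,
    )
    return traj, labels


def rigid_transform(rng):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng)).as_matrix()
    trans = np.random.default_rng(rng).uniform(-10, 10, 3)
    return rot, trans
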