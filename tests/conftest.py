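import numpy as np
import pytest

from statescape import (
    BasinPartition,
    EnergyTable,
    PlantedLandscapeSpec,
    assign_to_basins,
    make_planted_model,
)


@pytest.fixture
def two_roi_landscape() -> EnergyTable:
    """The worked n=2 landscape: E(00)=-1, E(01)=0.5, E(10)=0.7, E(11)=-0.8.

    (bit strings written ROI0-first; code = sum of bit_i * 2^i)
    """
    return EnergyTable(
        energies=np.array([-1.0, 0.5, 0.7, -0.8]), kind="model", n=2
    )


@pytest.fixture(scope="session")
def planted6():
    """A planted 6-region model with pattern 111000 and its landscape."""
    spec = PlantedLandscapeSpec(
        n_rois=6, pattern=(1, 1, 1, 0, 0, 0), coupling_strength=1.2
    )
    return make_planted_model(spec)


@pytest.fixture
def two_cluster_partition() -> BasinPartition:
    """Hand-built two-basin partition on n=3: states 0-3 -> basin 0, 4-7 -> basin 7.

    Gives both major basins a non-trivial periphery, which the dynamics
    counting rules need for their worked examples.
    """
    assignment = np.array([0, 0, 0, 0, 7, 7, 7, 7])
    part = BasinPartition(
        basin_codes=[0, 7],
        assignment=assignment,
        energies=np.array([-2.0, -1.5]),
        n=3,
        major=[0, 7],
    )
    return part


def random_landscape(rng: np.random.Generator, n: int = 4) -> EnergyTable:
    """A model-kind energy table with i.i.d. normal energies (no exact ties)."""
    return EnergyTable(energies=rng.normal(size=2**n), kind="model", n=n)
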