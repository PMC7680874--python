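import numpy as np
import pytest

from alffmvpa.simulate import CohortConfig, EffectCluster, generate_cohort
from alffmvpa.spatial import Mask, VolumeGrid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_grid():
    """5x5x5 grid at 3-mm isotropic voxels."""
    return VolumeGrid.isotropic((5, 5, 5), 3.0)


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject cohort with one strong planted cluster (fast unit tests)."""
    cfg = CohortConfig(
        n_patients=8, n_controls=8, n_completers=8,
        grid=VolumeGrid.isotropic((14, 16, 14), 3.0),
        effect_clusters=[EffectCluster(center_index=(8, 6, 7), radius_mm=9.0,
                                       group_effect_d=2.5, outcome_beta=1.0,
                                       outcome="vas")],
        seed=42)
    return generate_cohort(cfg)


def full_mask(grid: VolumeGrid) -> Mask:
    return Mask(grid, np.ones(grid.dims, dtype=bool))
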