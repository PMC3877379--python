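import numpy as np
import pytest

from patreg.imaging_io import BrainMask, BrainVolume, VolumeGrid
from patreg.synthetic_data import ModalityConfig, SyntheticConfig, generate_cohort


@pytest.fixture
def grid16():
    return VolumeGrid.isotropic((16, 16, 16), voxel_mm=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ball_mask(grid16):
    idx = np.indices(grid16.shape)
    c = (np.asarray(grid16.shape) - 1) / 2
    d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
    return BrainMask(grid=grid16, data=d2 <= 6.5**2)


def small_cohort_config(seed=0, n_subjects=24, **kw):
    """Desk-scale test cohort: 20^3 grid, one planted region per modality."""
    defaults = dict(
        n_subjects=n_subjects,
        shape=(20, 20, 20),
        modalities={
            m: ModalityConfig(n_regions=1, region_radius_vox=2.5)
            for m in ("GM", "WM", "PET")
        },
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


def random_volume(grid, rng, modality="GM"):
    return BrainVolume(grid=grid, data=rng.standard_normal(grid.shape), modality=modality)
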