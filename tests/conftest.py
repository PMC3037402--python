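import numpy as np
import pytest

from rsnparc import GridSpec, make_rsfmri_cohort
from rsnparc.core import _raster


def raster_flatten(maps: np.ndarray) -> np.ndarray:
    """Flatten (K, nx, ny, nz) truth maps in the same x-fastest order as
    rsnparc.core.flatten, so spatial correlations are comparable."""
    return _raster(maps)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(dims=(14, 16, 12), voxel_size=(3.0, 3.0, 4.0), tr=3.0)


@pytest.fixture(scope="session")
def desk_grid() -> GridSpec:
    # desk-scale analogue of the 53x63x35 acquisition grid
    return GridSpec(dims=(20, 24, 18), voxel_size=(3.0, 3.0, 4.0), tr=3.0)


@pytest.fixture(scope="session")
def ica_cohort(desk_grid):
    """12-subject, 6-network cohort at noise SD = 0.5 x signal (shared across
    ICA/stability tests to keep the suite fast)."""
    images, truth = make_rsfmri_cohort(
        desk_grid, n_subjects_per_group=6, n_networks=6, seed=3,
        n_timepoints=100, noise_sd=0.5,
    )
    return images, truth


@pytest.fixture(scope="session")
def ica_fit(ica_cohort):
    """GroupICA + reduced data fitted on the preprocessed shared cohort."""
    from rsnparc import GroupICA, detrend_bandpass, flatten, smooth_gaussian

    images, truth = ica_cohort
    mats = [flatten(smooth_gaussian(detrend_bandpass(im), 6.0)) for im in images]
    ica = GroupICA(n_components=12, random_state=0).fit(
        mats, subject_ids=[im.subject_id for im in images]
    )
    return ica, truth
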