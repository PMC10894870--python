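import warnings

import numpy as np
import pytest

from gbmrad.synthcohort import PhantomParams, SurvivalGenParams, generate_subject
from gbmrad.volume import RoiMask, Volume

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


TINY_PHANTOM = PhantomParams(grid_shape=(24, 24, 20), cavity_radius_mm=6.0,
                             lesion_radius_mm=3.0, ctv_margin_mm=4.0)


@pytest.fixture(scope="session")
def phantom_pair():
    """One lesion-bearing and one lesion-free noise-free phantom subject."""
    surv = SurvivalGenParams()
    with_lesion = generate_subject(
        PhantomParams(**{**TINY_PHANTOM.__dict__,
                         "lesion_prob": 1.0, "noise_sd": (0.0, 0.0)}),
        surv, seed=11)
    without = generate_subject(
        PhantomParams(**{**TINY_PHANTOM.__dict__,
                         "lesion_prob": 0.0, "noise_sd": (0.0, 0.0)}),
        surv, seed=11)
    return with_lesion, without


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_roi_volume(rng):
    """Random 5x5x5 volume with an irregular ROI for oracle comparisons."""
    data = rng.normal(size=(5, 5, 5))
    mask = rng.uniform(size=(5, 5, 5)) < 0.7
    mask[2, 2, 2] = True
    return Volume(data, (1.0, 1.0, 1.0)), RoiMask(mask, (1.0, 1.0, 1.0))
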