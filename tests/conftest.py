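import numpy as np
import pytest

from fetrad.parametric import default_schedule
from fetrad.radiomics.preprocess import DiscretizedROI, ResampledROI
from fetrad.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless aggressive-phenotype phantom (image, tumor mask, bg mask)."""
    return generate_phantom(PhantomSpec(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(seed=7))


def make_disc(levels: np.ndarray, mask: np.ndarray = None) -> DiscretizedROI:
    """Wrap an integer level array (0 = outside mask) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    return DiscretizedROI(
        levels=np.where(mask, levels, 0),
        mask=mask.astype(bool),
        bin_width=1.0,
        level_count=int(levels[mask].max()),
    )


def random_disc(rng: np.random.Generator, shape=(5, 5, 5), ng=4, hole_prob=0.2):
    """Random discretized ROI with mask holes, for oracle comparisons."""
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) >= hole_prob
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return make_disc(levels, mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_roi(values: np.ndarray, mask: np.ndarray = None, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return ResampledROI(values=values, mask=mask.astype(bool), spacing=spacing)
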