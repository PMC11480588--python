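import numpy as np
import pytest

from stemleaf.cloud import PointCloud, normalize
from stemleaf.synthetic import SyntheticPlantSpec, generate_plant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """64 random points with binary labels."""
    return PointCloud(
        points=rng.normal(size=(64, 3)),
        semantic_labels=rng.integers(0, 2, 64),
    )


@pytest.fixture(scope="session")
def small_plant():
    """One noise-free synthetic plant (512 points, 4 leaves) plus ground truth."""
    spec = SyntheticPlantSpec(points_total=512, n_leaves=4, surface_noise_sd=0.0, seed=7)
    return generate_plant(spec)


@pytest.fixture(scope="session")
def normalized_plant(small_plant):
    cloud, _ = small_plant
    norm, t = normalize(cloud)
    return norm, t
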