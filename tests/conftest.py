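import numpy as np
import pytest

from germquant.boxes import BoundingBox
from germquant.simulate import DiskSpec, sample_disk, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """A fast, exactly-counted disk: 20 seeds, half germinated."""
    return DiskSpec(
        image_size=(256, 256),
        n_seeds=20,
        germination_fraction=0.5,
        exact_counts=True,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return sample_disk(small_spec)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """10 small annotated disks with a 6/2/2 split, written once per session."""
    root = tmp_path_factory.mktemp("disks")
    spec = DiskSpec(image_size=(256, 256), n_seeds=25, radicle_contrast=0.8,
                    overlap_intensity=0.0, rng_seed=7)
    return generate_dataset(spec, 10, "S_R", root)


def random_box(rng, lo=0.0, hi=100.0, min_size=1.0):
    x0, y0 = rng.uniform(lo, hi - min_size, 2)
    w, h = rng.uniform(min_size, hi - max(x0, y0), 2)
    return BoundingBox(x0, y0, x0 + w, y0 + h)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
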