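import numpy as np
import pytest
from hypothesis import settings

from sparsemil.synthetic import SyntheticConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mini_config():
    """Small synthetic scenario: 258-px images, 9 patches of side 86."""
    return SyntheticConfig(
        image_side=258,
        patch_side=86,
        n_patients=8,
        images_per_patient=(1, 2),
        abnormal_patches_per_positive=(1, 2),
        fov_radius_fraction=0.71,
        seed=7,
    )


def tiny_bags(n_bags=6, n_patches=4, side=32, seed=0, contrast=0.95, background=0.05):
    """Hand-built tiny bags: positives carry one bright patch on dark noise.

    Used for fast training-loop tests where the synthetic generator's
    full-size images would be overkill.
    """
    from sparsemil.bags import Bag

    rng = np.random.default_rng(seed)
    bags = []
    for i in range(n_bags):
        label = i % 2
        patches = rng.uniform(0.0, background, size=(n_patches, side, side, 3)).astype(np.float32)
        if label:
            patches[rng.integers(n_patches)] += contrast
        bags.append(Bag(patches=np.clip(patches, 0, 1), label=label,
                        patient_id=f"T{i}", grid_shape=(1, n_patches)))
    return bags
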