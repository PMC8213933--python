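import numpy as np
import pytest

from caphier import (
    build_volume_matrix,
    cosine_distance_matrix,
    cut_levels,
    generate_dataset,
    ward_linkage,
)
from caphier.synthetic import effect_preset


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-group dataset with a known injected effect (shared)."""
    cfg = effect_preset(seed=42, n_subjects_per_group=4, n_volumes=40,
                        grid_shape=(12, 12, 10), n_networks=4,
                        affected_networks=(0,))
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_vm(small_dataset):
    return build_volume_matrix(small_dataset)


@pytest.fixture(scope="session")
def small_tree(small_vm):
    return ward_linkage(cosine_distance_matrix(small_vm))


@pytest.fixture(scope="session")
def small_labeling(small_tree):
    return cut_levels(small_tree, 2, 30)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
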