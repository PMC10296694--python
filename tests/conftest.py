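import numpy as np
import pytest

from nucleomorph import (
    default_benign_spec,
    default_malignant_spec,
    generate_dataset,
)
from nucleomorph.pipeline import extract_table


@pytest.fixture(scope="session")
def small_dataset():
    """A 10+10 image synthetic dataset shared across tests."""
    return generate_dataset(
        default_benign_spec(), default_malignant_spec(), n_per_class=10, seed=11
    )


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    ds = small_dataset
    return extract_table(ds.images, ds.label_maps, ds.class_labels)


def random_label_map(rng: np.random.Generator, shape=(20, 20), p=0.4):
    """Random labelled blobs for oracle-equivalence tests."""
    from scipy import ndimage as ndi

    mask = rng.uniform(size=shape) < p
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels
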