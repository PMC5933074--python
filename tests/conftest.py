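import numpy as np
import pytest

from sparsedecode.classifiers import LabeledDictionary, SolverSettings
from sparsedecode.simdata import generate_group


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_settings():
    """Loose-but-adequate solver settings for streaming tests."""
    return SolverSettings(tau_scale=0.2, tol=1e-3, max_iter=100)


def make_class_templates(rng, n_features=30, n_classes=3, separation=4.0):
    """Well-separated random class template vectors."""
    templates = rng.standard_normal((n_classes, n_features))
    templates /= np.linalg.norm(templates, axis=1, keepdims=True)
    return separation * templates


def make_toy_dictionary(rng, n_features=30, n_classes=3, per_class=8, noise=0.5,
                        separation=4.0):
    """Labeled dictionary of noisy copies of class templates."""
    templates = make_class_templates(rng, n_features, n_classes, separation)
    cols, labels = [], []
    for c in range(n_classes):
        for _ in range(per_class):
            cols.append(templates[c] + noise * rng.standard_normal(n_features))
            labels.append(c + 1)
    A = np.array(cols).T
    return LabeledDictionary(A, np.array(labels)), templates


@pytest.fixture
def toy_dictionary(rng):
    dictionary, _ = make_toy_dictionary(rng)
    return dictionary


@pytest.fixture(scope="session")
def tiny_collection_g1():
    """Small group-1 collection shared by pipeline-level tests."""
    return generate_group(
        1,
        n_subjects=2,
        cnr_levels=[0.10, 0.16],
        master_seed=7,
        grid_shape=(16, 16),
        paradigm_kwargs={"block_length_task": 16.0, "block_length_rest": 8.0,
                         "n_blocks_per_task": 2},
    )
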