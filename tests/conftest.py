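import numpy as np
import pytest

from rosenose import (
    build_feature_matrix,
    default_config,
    generate_dataset,
    load_reference_profiles,
    normalize_columns,
    rank_features,
)


@pytest.fixture(scope="session")
def reference_profiles():
    return load_reference_profiles()


@pytest.fixture(scope="session")
def default_dataset():
    """The full stated world: 10 genotypes x 15 replicates, seed 0."""
    measurements, labels, profiles = generate_dataset(default_config())
    return measurements, labels, profiles


@pytest.fixture(scope="session")
def default_features(default_dataset):
    measurements, labels, _ = default_dataset
    return build_feature_matrix(measurements, labels)


@pytest.fixture(scope="session")
def normalized_features(default_features):
    fm, _ = normalize_columns(default_features)
    return fm


@pytest.fixture(scope="session")
def default_ranking(normalized_features):
    return rank_features(normalized_features)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 genotypes (one per class) x 3 replicates: 9 measurements."""
    cfg = default_config(
        n_genotypes=3,
        replicates_per_genotype=3,
        genotype_classes=("C1", "C2", "C3"),
        genotype_coords={"g1": (0.24, 0.24), "g2": (0.06, 0.45), "g3": (0.45, 0.06)},
        rng_seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
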