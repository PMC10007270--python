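"""Shared fixtures: synthetic datasets and trained models at desk scale.

Everything is generated programmatically with fixed seeds; the expensive
artifacts (feature tables, trained two-stage models) are session-scoped so
the whole suite trains each model exactly once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from seedage.descriptors import extract_features_table
from seedage.imagedata import SyntheticSpec, generate_dataset, generate_seed_image
from seedage.pipeline import BoosterConfig, split_dataset, train_two_stage

DESK_SCALE = 0.1
SEED = 0


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(rng_seed=SEED)


@pytest.fixture(scope="session")
def easy_spec() -> SyntheticSpec:
    return SyntheticSpec.easy(rng_seed=SEED)


def _build_features(spec, tmp_root):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = generate_dataset(spec, tmp_root, scale=DESK_SCALE)
        features = extract_features_table(manifest, tmp_root)
        features = split_dataset(features, ratio=0.7, rng_seed=SEED)
    return manifest, features


@pytest.fixture(scope="session")
def desk_data(default_spec, tmp_path_factory):
    """(manifest, split feature table) of the desk-scale default dataset."""
    return _build_features(default_spec, tmp_path_factory.mktemp("desk"))


@pytest.fixture(scope="session")
def easy_data(easy_spec, tmp_path_factory):
    """(manifest, split feature table) of the wide-separation dataset."""
    return _build_features(easy_spec, tmp_path_factory.mktemp("easy"))


@pytest.fixture(scope="session")
def desk_model(desk_data):
    _, features = desk_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_two_stage(features, BoosterConfig(), seed=SEED)


@pytest.fixture(scope="session")
def easy_model(easy_data):
    _, features = easy_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_two_stage(features, BoosterConfig(), seed=SEED)


@pytest.fixture
def crop(default_spec):
    """One segmented synthetic seed crop."""
    from seedage.imagedata import crop_seed, remove_background

    image, _ = generate_seed_image(default_spec, "Koshihikari", 2016, SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = remove_background(image)
    return crop_seed(image, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
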