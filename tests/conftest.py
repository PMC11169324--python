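import dataclasses

import numpy as np
import pytest

from camval import (MontageSettings, PhantomConfig, TrainConfig, ModelSpec,
                    default_profiles, generate_dataset, train)
from camval.phantom import _default_features


def tiny_phantom_config(seed: int = 7) -> PhantomConfig:
    """32-px phantom for unit tests; fewer blobs fit the miniature lungs."""
    feats = dict(_default_features())
    feats["consolidation"] = dataclasses.replace(feats["consolidation"],
                                                 count=(1, 2))
    return PhantomConfig(image_size=32, slices_per_case=12,
                         feature_params=feats, seed=seed)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return tiny_phantom_config()


@pytest.fixture(scope="session")
def small_montage_settings() -> MontageSettings:
    return MontageSettings(count=4, interval=2, layout=(2, 2),
                           train_montages_per_case=1, test_montages_per_case=2)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_montage_settings):
    return generate_dataset(small_config, n_pos=8, n_neg=8,
                            profiles=default_profiles(3), seed=11,
                            montage_settings=small_montage_settings,
                            n_test=(3, 3))


@pytest.fixture(scope="session")
def trained_small(small_bundle):
    """A briefly trained tiny model on the unit-test phantom (not accurate)."""
    spec = ModelSpec(input_size=(64, 64), seed=5)
    cfg = TrainConfig(seed=5, max_epochs=4, patience=3, val_fraction=0.25,
                      batch_size=8)
    return train(spec, cfg, montages=small_bundle.train_montages)
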