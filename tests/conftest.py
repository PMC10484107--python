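"""Shared fixtures: small rendered scenes and a quickly trained classifier."""

from __future__ import annotations

import numpy as np
import pytest

from seedqc import arch, synthgen, traineval


@pytest.fixture(scope="session")
def small_scene() -> synthgen.LabeledScene:
    """An 8-seed scene with both classes, well separated."""
    spec = synthgen.SceneSpec(
        n_seeds=8, defect_fraction=0.5, min_separation=30.0, rng_seed=7
    )
    return synthgen.render_scene(spec)


@pytest.fixture(scope="session")
def crop_data() -> tuple[np.ndarray, np.ndarray]:
    """Balanced 64 px crops (120 per class) for classifier tests."""
    return synthgen.make_crop_dataset(120, crop_size=64, rng_seed=11)


@pytest.fixture(scope="session")
def tiny_model_config() -> arch.ModelConfig:
    return arch.ModelConfig(input_size=64, stages=((1, 8), (1, 8), (1, 8)), rng_seed=3)


@pytest.fixture(scope="session")
def trained_model(tmp_path_factory, tiny_model_config) -> arch.SeedClassifier:
    """A small classifier trained on crops cut from rendered tray scenes."""
    data_dir = tmp_path_factory.mktemp("train_scenes")
    spec = synthgen.SceneSpec(n_seeds=10, defect_fraction=0.5, min_separation=30.0)
    train_df, test_df = synthgen.make_dataset(spec, 25, data_dir, rng_seed=3)
    model = arch.build_model(tiny_model_config)
    config = traineval.TrainConfig(
        batch_size=32, epochs=15, rng_seed=3, stop_accuracy=0.98
    )
    traineval.train(model, train_df, config, test_manifest=test_df)
    return model
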