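import numpy as np
import pytest

from desertveg import RunConfig, simulate_dataset
from desertveg.config import TrainParams
from desertveg.simulate import discriminating_scene_params, easy_scene_params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_benchmark(tmp_path_factory):
    """A 6-scene 128x128 shadow-free benchmark for fast pipeline tests."""
    d = tmp_path_factory.mktemp("tiny_bench")
    cfg = RunConfig(
        simulate=easy_scene_params(size=(128, 128), blob_radius=(6.0, 12.0)),
        train=TrainParams(
            C_grid=(1.0, 100.0),
            gamma_grid=(0.1, 1.0),
            max_samples_per_class_per_image=120,
            seed=7,
        ),
        seed=7,
    )
    manifest = simulate_dataset(d, 6, cfg)
    return d, cfg, manifest


@pytest.fixture(scope="session")
def easy_benchmark(tmp_path_factory):
    """The 10-scene 256x256 easy benchmark (no distractors, no shadows)."""
    d = tmp_path_factory.mktemp("easy_bench")
    cfg = RunConfig(
        simulate=easy_scene_params(size=(256, 256), seed=0),
        train=TrainParams(max_samples_per_class_per_image=250, seed=0),
        seed=0,
    )
    manifest = simulate_dataset(d, 10, cfg)
    return d, cfg, manifest


@pytest.fixture(scope="session")
def discriminating_benchmark(tmp_path_factory):
    """The 10-scene 256x256 benchmark with shadows and green flat distractors."""
    d = tmp_path_factory.mktemp("disc_bench")
    cfg = RunConfig(
        simulate=discriminating_scene_params(size=(256, 256), seed=0),
        train=TrainParams(max_samples_per_class_per_image=250, seed=0),
        seed=0,
    )
    manifest = simulate_dataset(d, 10, cfg)
    return d, cfg, manifest
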