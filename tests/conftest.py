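import numpy as np
import pytest

from stainadapt import (
    ClassMotif,
    DomainTransform,
    SyntheticSpec,
    TrainingConfig,
    EnhancerPolicy,
    build_model,
    generate_dataset,
)


def random_patch_pixels(rng, h=8, w=8, lo=0.0, hi=1.0):
    return lo + (hi - lo) * rng.random((h, w, 3))


@pytest.fixture(scope="session")
def micro_spec():
    """A miniature two-domain dataset spec: 2 classes x 4 slides x 4 patches
    of 32x32, enough structure for fast training tests."""
    return SyntheticSpec(
        n_classes=2,
        slides_per_class=4,
        patches_per_slide=4,
        patch_px=32,
        slide_px=64,
        seed=7,
    )


@pytest.fixture(scope="session")
def micro_dataset(micro_spec):
    return generate_dataset(micro_spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The benchmark-default dataset (generated once per session)."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture()
def micro_config():
    return TrainingConfig(
        learning_rate=1e-3,
        batch_size=16,
        max_epochs=2,
        patience=2,
        backbone="tiny",
        input_px=32,
        enhancer=EnhancerPolicy(probability=0.5),
        seeds=(0,),
    )


@pytest.fixture()
def tiny_model(micro_config):
    return build_model(micro_config, n_classes=2, tap_block=4, seed=0)
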