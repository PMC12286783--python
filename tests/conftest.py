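import numpy as np
import pytest

from volseg import (
    EncoderConfig,
    ModelConfig,
    OrganSpec,
    PhantomSpec,
    SegmentationModel,
    generate_phantom,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_phantom():
    """One 32^3 two-class sphere phantom (mild noise, slight blur)."""
    spec = PhantomSpec(
        grid=(32, 32, 32), channels=1, num_classes=2,
        organs=[OrganSpec(1, "ellipsoid", (0.5, 0.5, 0.5), (0.3, 0.3, 0.3))],
        intensity_table=np.array([[0.0], [100.0]]),
        noise_sigma=5.0, blur_sigma=0.5,
    )
    return generate_phantom(spec, seed=0)


def tiny_encoder_config(**overrides) -> EncoderConfig:
    """Reduced-width 4-stage config used across the tests."""
    kwargs = dict(
        stage_channels=(8, 16, 32, 64),
        blocks_per_stage=(1, 1, 1, 1),
        heads=(2, 2, 2, 2),
        base_input_shape=(32, 32, 32),
    )
    kwargs.update(overrides)
    return EncoderConfig(**kwargs)


def micro_encoder_config(**overrides) -> EncoderConfig:
    """Three-stage micro config (min input 16^3) for fast train tests."""
    kwargs = dict(
        stage_channels=(4, 8, 16),
        blocks_per_stage=(1, 1, 1),
        heads=(1, 1, 1),
        base_input_shape=(16, 16, 16),
    )
    kwargs.update(overrides)
    return EncoderConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_model(sphere_phantom):
    cfg = ModelConfig(encoder=tiny_encoder_config(), in_channels=1,
                      num_classes=2, init_seed=0)
    return SegmentationModel(cfg)


@pytest.fixture(scope="session")
def micro_phantoms():
    """Four 16^3 two-class phantoms for micro training runs."""
    spec = PhantomSpec(
        grid=(16, 16, 16), channels=1, num_classes=2,
        organs=[OrganSpec(1, "ellipsoid", (0.5, 0.5, 0.5), (0.3, 0.3, 0.3))],
        intensity_table=np.array([[0.0], [100.0]]),
        noise_sigma=5.0, blur_sigma=0.0, center_jitter=0.05,
    )
    return [generate_phantom(spec, seed=s) for s in range(4)]
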