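"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from fangmark import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.GeneratorConfig:
    """Desk-scale generator config used across the suite."""
    return sd.GeneratorConfig(image_size=64)


@pytest.fixture(scope="session")
def cobra_image(small_config) -> sd.LabeledImage:
    return sd.generate_bite_image(sd.COBRA, small_config, seed=7)


@pytest.fixture(scope="session")
def other_image(small_config) -> sd.LabeledImage:
    return sd.generate_bite_image(sd.OTHER, small_config, seed=7)


@pytest.fixture(scope="session")
def darkened_fixture(small_config) -> np.ndarray:
    """A synthetic image scaled down to 30% brightness; the enhancement
    stage must brighten it."""
    image = sd.generate_bite_image(sd.COBRA, small_config, seed=11)
    return image.pixels * 0.3


@pytest.fixture(scope="session")
def tiny_dataset(small_config) -> list[sd.LabeledImage]:
    """200 images (100 per class), seed 0, used by training tests."""
    return sd.generate_dataset(100, 100, small_config, seed=0)
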