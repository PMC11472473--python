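import dataclasses

import numpy as np
import pytest

from sfida.simulate import ImagingParams


@pytest.fixture
def small_params() -> ImagingParams:
    """Reduced acquisition geometry used throughout the suite for runtime;
    the noise/spot model is the default study model."""
    return ImagingParams(image_height=120, image_width=120, images_per_well=5, seed=11)


@pytest.fixture
def tiny_params() -> ImagingParams:
    return ImagingParams(image_height=40, image_width=40, images_per_well=3, seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def reseed(params: ImagingParams, seed: int) -> ImagingParams:
    return dataclasses.replace(params, seed=seed)
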