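from __future__ import annotations

import numpy as np
import pytest

from phaquant.imaging import ChannelImage
from phaquant.quantify import ConversionParams, QuantConfig
from phaquant.simulate import NoiseModel, SceneConfig, generate_scene


def make_channel(pixels, role="DNA", bit_depth=8) -> ChannelImage:
    return ChannelImage(pixels=np.asarray(pixels, dtype=np.int64), bit_depth=bit_depth, role=role)


@pytest.fixture(scope="session")
def noiseless_scene():
    """A 30-cell noiseless field with ground truth (session-cached: read-only)."""
    cfg = SceneConfig(n_cells=30, noise=NoiseModel("none"), seed=42)
    return generate_scene(cfg)


@pytest.fixture
def per_granule_config() -> QuantConfig:
    """Pipeline config using the granule-wise volume conversion (matches 3-D truth)."""
    return QuantConfig(conversion=ConversionParams(volume_model="per_granule"))
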