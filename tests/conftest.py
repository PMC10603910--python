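from secpnet._runtime import configure_runtime

configure_runtime()

import numpy as np
import pytest

from secpnet import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cfg():
    """Tiny architecture used throughout: depth 2, narrow widths."""
    return NetworkConfig(
        num_classes=4,
        in_channels=1,
        depth=2,
        stage_channels=(4, 6, 8),
        se_reduction=2,
    )


@pytest.fixture
def preset_cfg():
    """The CPU preset: depth 3, widths 8/16/32/64, SE reduction 4."""
    return NetworkConfig.small(num_classes=5)
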