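import numpy as np
import pytest

from rnfl_quant import PhantomSpec


@pytest.fixture
def control_spec() -> PhantomSpec:
    return PhantomSpec.for_group("control")


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A 64×64 phantom for fast network tests (5 µm/px keeps the band inside)."""
    return PhantomSpec.for_group(
        "control", width_ascans=64, height_px=64, axial_spacing_um=5.0, ilm_depth_px=10
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
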