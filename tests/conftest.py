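import numpy as np
import pytest

from salseg import synth
from salseg.pipeline import PipelineConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smear_scene():
    """One deterministic easy smear image with its ground truth."""
    params = synth.SmearParams(seed=42)
    img, truth, nucleus = synth.generate_smear(params)
    return img, truth, nucleus


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config at the standard operating point, fixed seed."""
    return PipelineConfig(seed=7)


def block_label_map(block: int, grid: int) -> np.ndarray:
    """A (grid*block)^2 label image of square superpixels, labels row-major."""
    idx = np.arange(grid * block) // block
    return (idx[:, None] * grid + idx[None, :]).astype(int)
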