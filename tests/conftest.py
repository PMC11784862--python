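import numpy as np
import pytest

from efnet.data_io import EchoDataset
from efnet.model import ModelConfig
from efnet.phantom import generate_phantom_dataset

TINY_MODEL = ModelConfig(
    clip_len=8,
    height=16,
    width=16,
    stem_channels=4,
    stage_channels=(4, 8, 8, 8),
    n_heads=2,
    seed=3,
)


@pytest.fixture(scope="session")
def small_phantom_root(tmp_path_factory):
    """12 speckled 16x16 phantoms with 80/10/10 splits (shared, read-only)."""
    root = tmp_path_factory.mktemp("phantoms") / "ds"
    generate_phantom_dataset(
        12, seed=21, out_dir=root, image_size=16, cycle_frames=8, n_cycles=2
    )
    return root


@pytest.fixture(scope="session")
def small_phantom_dataset(small_phantom_root):
    return EchoDataset(small_phantom_root)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
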