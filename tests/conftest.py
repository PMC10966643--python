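from pathlib import Path

import numpy as np
import pytest

from affinet.egnn import EncoderParams, ModelConfig
from affinet.readout import ReadoutParams
from affinet.synthetic import OracleParams, make_complex

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def small_cfg() -> ModelConfig:
    """A deliberately tiny architecture for fast unit tests."""
    return ModelConfig(n_s=8, n_f=4, n_passes=2, n_hidden=16, readout_hidden=16)


@pytest.fixture()
def small_model(small_cfg):
    rng = np.random.default_rng(42)
    enc = EncoderParams(small_cfg, rng)
    ro = ReadoutParams(small_cfg, rng, shift=6.0)
    # non-zero output layers so invariance tests exercise real contributions
    out_rng = np.random.default_rng(7)
    for mlp in (ro.atom_mlp, ro.pair_mlp):
        last = mlp.layers[-1]
        last.W.data = out_rng.normal(0.0, 0.5, last.W.data.shape)
    return enc, ro


@pytest.fixture(scope="session")
def noiseless_oracle() -> OracleParams:
    return OracleParams(noise_sd=0.0)


@pytest.fixture()
def toy_complex():
    return make_complex(14, 6, seed=123, id="toy")


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
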