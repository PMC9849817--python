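import numpy as np
import pytest

from orchard_vqa.backbones import EncoderContract
from orchard_vqa.corpus import SynthConfig, generate_synthetic_corpus
from orchard_vqa.engine import encode_corpus


@pytest.fixture(scope="session")
def synth_corpus(tmp_path_factory):
    """20-image mixed-type corpus, all-train."""
    out = tmp_path_factory.mktemp("corpus")
    manifest, gen_params = generate_synthetic_corpus(
        SynthConfig(n_images=20, seed=7), out)
    return manifest, gen_params, out


@pytest.fixture(scope="session")
def yesno_count_corpus(tmp_path_factory):
    """20-image yes/no + counting corpus (small answer vocabulary)."""
    out = tmp_path_factory.mktemp("corpus_yn")
    manifest, gen_params = generate_synthetic_corpus(
        SynthConfig(n_images=20, image_size=128,
                    type_mix=(0.5, 0.5, 0.0, 0.0), seed=3), out)
    return manifest, gen_params, out


@pytest.fixture(scope="session")
def tiny_contract():
    return EncoderContract(name="tiny", output_channels=8, grid_side=4, seed=0)


@pytest.fixture(scope="session")
def yesno_features(yesno_count_corpus, tiny_contract):
    manifest, _, root = yesno_count_corpus
    return encode_corpus(manifest, contract=tiny_contract, q_dim=16, seed=0,
                         image_root=root)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
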