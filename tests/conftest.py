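import numpy as np
import pytest

from epifold import ChainParams, InteractionModel, make_block_sequence


@pytest.fixture(scope="session")
def toy_seq():
    """The 120-monomer (A10B10)6 block copolymer."""
    return make_block_sequence([("A", 10), ("B", 10)], 6)


@pytest.fixture(scope="session")
def small_seq():
    """A 20-monomer (A5B5)2 copolymer for fast solver/MD runs."""
    return make_block_sequence([("A", 5), ("B", 5)], 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140804)


def ideal_model(alphabet):
    """Interaction model of a truly non-interacting (phantom) chain:
    no attractions, no MD excluded volume, no SCA surrogate."""
    return InteractionModel.uniform(
        0.0,
        0.0,
        alphabet,
        chain=ChainParams(hardcore_md=("wca", 1.0, 0.0), hardcore_sca=(0.0, 1.0)),
    )


@pytest.fixture(scope="session")
def ideal_model_small(small_seq):
    return ideal_model(small_seq.alphabet)


def write_bed(path, rows):
    path.write_text("".join(f"{c}\t{s}\t{e}\t{lab}\n" for c, s, e, lab in rows))
    return path
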