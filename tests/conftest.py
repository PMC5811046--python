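import numpy as np
import pytest

from polypro.motifs import default_rule_table
from polypro.simulate import ECOLI_AA_FREQS


@pytest.fixture(scope="session")
def rules():
    return default_rule_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_sequences(rng, n, length, f_p=0.05):
    """i.i.d. sequences over a reduced alphabet with the given proline freq."""
    letters = np.array(list("PAGLKV"))
    probs = np.array([f_p] + [(1 - f_p) / 5] * 5)
    draws = rng.choice(6, size=(n, length), p=probs)
    return ["".join(letters[row]) for row in draws]


@pytest.fixture(scope="session")
def ecoli_freqs():
    total = sum(ECOLI_AA_FREQS.values())
    return {k: v / total for k, v in ECOLI_AA_FREQS.items()}
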