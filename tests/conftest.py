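import itertools

import numpy as np
import pytest

from kinothread import AlignedSequence, PottsModel
from kinothread.synthetic import make_toy_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model():
    """Random L=6, q=4 zero-mean model with dense-ish couplings."""
    return make_toy_model(L=6, q=4, sparsity=0.8, coupling_scale=1.0, seed=7)


def random_sequence(model: PottsModel, rng) -> AlignedSequence:
    return AlignedSequence("".join(rng.choice(list(model.alphabet),
                                              size=model.L)))


def naive_energy(model: PottsModel, symbols: str) -> float:
    """Independent double-loop total-energy oracle."""
    idx = {c: k for k, c in enumerate(model.alphabet)}
    s = [idx[c] for c in symbols]
    e = 0.0
    for i in range(model.L):
        e += model.fields[i][s[i]]
        for j in range(i + 1, model.L):
            e += model.J(i, j)[s[i], s[j]]
    return e


def all_sequences(model: PottsModel):
    for combo in itertools.product(model.alphabet, repeat=model.L):
        yield "".join(combo)
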