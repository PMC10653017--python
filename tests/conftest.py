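import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from passreg.data import LabeledSet, UnlabeledSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_labeled(rng, n=40, p=4, beta=None, gamma=0.8, zeta=-0.5):
    """Small logistic-model labeled set for solver-level tests."""
    X = rng.standard_normal((n, p))
    S = rng.poisson(2.0, n).astype(float)
    if beta is None:
        beta = np.zeros(p)
        beta[: min(2, p)] = (1.0, -0.8)[: min(2, p)]
    eta = zeta + gamma * S + X @ beta
    Y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if Y.min() == Y.max():  # force both classes for tiny n
        Y[0], Y[1] = 0.0, 1.0
    return LabeledSet(Y, S, X, [f"X{j+1}" for j in range(p)])


@pytest.fixture
def small_labeled(rng):
    return make_labeled(rng)


@pytest.fixture
def small_unlabeled(rng):
    X = rng.standard_normal((60, 4))
    S = rng.poisson(2.0, 60).astype(float)
    return UnlabeledSet(S, X, [f"X{j+1}" for j in range(4)])
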