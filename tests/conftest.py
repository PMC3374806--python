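"""Shared fixtures: filter bank, cached C1 maps, toy C1 factories."""

import warnings

import numpy as np
import pytest

from artmax.hierarchy import C1Maps, build_gabor_bank, compute_c1
from artmax.synthetic import make_benchmark


@pytest.fixture(scope="session")
def bank():
    return build_gabor_bank()


@pytest.fixture(scope="session")
def bench20(bank):
    """A small benchmark: 20 mixed training images, 8 clean test images."""
    return make_benchmark(n_faces=4, n_distractors=4, noise_levels=(0.0,),
                          seed=5, n_train_per_class=10)


@pytest.fixture(scope="session")
def stream20_c1(bank, bench20):
    """C1 maps of the 20-image mixed training stream (computed once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [compute_c1(im, bank) for im in bench20.train_images]


@pytest.fixture(scope="session")
def test8_c1(bank, bench20):
    images, labels = bench20.test_sets[0.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [compute_c1(im, bank) for im in images], labels


def make_toy_c1(rng, shapes=((30, 30), (18, 18))):
    """A synthetic C1 stack with the given per-band grid shapes."""
    return C1Maps(bands=tuple(
        rng.random((h, w, 4)) for h, w in shapes))


@pytest.fixture
def toy_c1():
    return make_toy_c1(np.random.default_rng(42))
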