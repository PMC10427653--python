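import numpy as np
import pytest

from cadkit.strategies import ALL_PAIRS, canonical_sort


class AlwaysFixedChooser:
    """Always takes the 2-EUR anchor during titration (canonical first in
    the equal round, where neither side is flexible yet)."""

    def choose(self, offer, rng):
        if offer.flexible is None:
            return canonical_sort(offer.strategies)[0]
        return next(s for s in offer.strategies if s != offer.flexible)


class AlwaysFlexibleChooser:
    """Always keeps the titrated strategy."""

    def choose(self, offer, rng):
        if offer.flexible is None:
            return canonical_sort(offer.strategies)[0]
        return offer.flexible


@pytest.fixture
def pair():
    return ALL_PAIRS[0]


@pytest.fixture
def always_fixed():
    return AlwaysFixedChooser()


@pytest.fixture
def always_flexible():
    return AlwaysFlexibleChooser()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
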