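import logging

import numpy as np
import pytest

from corrfdr import SortedScreenInput, illustration_example

# keep per-procedure INFO lines quiet during the suite (tests that assert
# on the logging contract re-enable capture explicitly)
logging.getLogger("corrfdr").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def example():
    """Eight-feature worked example: (SortedScreenInput, alpha=0.1)."""
    return illustration_example()


def random_sorted_input(rng, P=None, with_r=True):
    """A random valid SortedScreenInput for property checks."""
    if P is None:
        P = int(rng.integers(1, 40))
    p = np.sort(rng.uniform(0, 1, size=P))
    r = rng.uniform(-1, 1, size=P - 1) if with_r else None
    return SortedScreenInput.from_pvalues(p, r)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
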