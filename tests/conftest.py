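import numpy as np
import pytest

from frocfit import (
    ConfidenceCounts,
    CriteriaVector,
    FitConfig,
    ItemClass,
    MixtureParams,
    RatingScale,
)

CRITERIA = CriteriaVector(np.array([-1.5, -0.75, 0.0, 0.75, 1.5]))


@pytest.fixture
def criteria():
    return CRITERIA


@pytest.fixture
def scale6():
    return RatingScale(k_levels=6)


@pytest.fixture
def example_counts(scale6):
    """A small hand-checkable lure/new count pair on the 6-point scale."""
    lure = ConfidenceCounts(ItemClass.LURE, np.array([10, 5, 5, 10, 20, 50]), scale6)
    new = ConfidenceCounts(ItemClass.NEW, np.array([50, 20, 10, 5, 5, 10]), scale6)
    return lure, new


@pytest.fixture
def fast_config():
    """Few starts: enough for well-behaved unit-test problems, fast."""
    return FitConfig(n_starts=5, seed=0)


@pytest.fixture
def typical_params():
    return MixtureParams(r_false=0.2, r_reject=0.25, d_prime=1.0)
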