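import numpy as np
import pytest

from emoroc.cohort import ObserverProfile
from emoroc.design import build_design, synthetic_catalog


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog()


@pytest.fixture(scope="session")
def design(catalog):
    return build_design(catalog, "P01", seed=11)


@pytest.fixture
def make_profile():
    """Observer factory with sensible defaults for simulation tests."""

    def _make(dprime=0.75, pid="P01", trait=35, criterion=None, **kwargs):
        if not isinstance(dprime, dict):
            dprime = {e: float(dprime) for e in ("HA", "NE", "FE", "DI")}
        if criterion is not None:
            kwargs["decision_criterion"] = criterion
        return ObserverProfile(
            participant_id=pid,
            trait_score=trait,
            state_score=30,
            dprime=dprime,
            **kwargs,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
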