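import numpy as np
import pytest

from radkit.analysis import ReferenceSet
from radkit.synthetic_fixtures import FixtureSpec, generate_reference_fixture

REFERENCE_SEED = 20220


@pytest.fixture(scope="session")
def ref_fixture():
    """The deterministic synthetic reference triple."""
    return generate_reference_fixture(FixtureSpec(seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def reference(ref_fixture):
    """Reference set (classical structure + body/head frames) built from the
    synthetic triple."""
    return ReferenceSet.from_structures(
        ref_fixture.classical, ref_fixture.body_rotated, ref_fixture.head_rotated
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
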