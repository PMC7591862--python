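import numpy as np
import pytest

from canomap.anomaly import cohort_anomaly
from canomap.phantom import PhantomSpec, build_phantom
from canomap.simulate import SignalModel, simulate_control


@pytest.fixture(scope="session")
def tiny_phantom():
    """A minimal phantom (7 x 2 x (1 cerebral + 1 cerebellar) blocks)."""
    return build_phantom(
        PhantomSpec(shape=(8, 10, 8), cerebral_blocks_per_network=1,
                    cerebellar_blocks_per_network=1, seed=3)
    )


@pytest.fixture(scope="session")
def small_ph():
    from canomap.phantom import small_phantom

    return small_phantom(seed=1)


@pytest.fixture(scope="session")
def model_fast():
    return SignalModel(n_timepoints=150)


@pytest.fixture(scope="session")
def control_cohort(small_ph, model_fast):
    """Ten control scans on the small phantom, shared across tests."""
    return [
        simulate_control(small_ph, model_fast, seed=9000 + i, subject_id=f"c{i}")
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
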