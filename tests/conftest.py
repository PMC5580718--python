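import numpy as np
import pytest

from triophaser import pipeline


@pytest.fixture(scope="session")
def small_sim():
    """A 60-kb trio simulation shared by pipeline-level tests."""
    return pipeline.simulate_trio(
        seed=7, length=60_000, n_founders=12, fragments=(1, 3), min_aligned=10_000
    )


@pytest.fixture(scope="session")
def small_outcome(small_sim):
    from triophaser import phase_simulated_trio

    return phase_simulated_trio(small_sim, rounds=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
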