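import pytest

from chtriage import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A simulated cohort shared by cohort-level tests.

    Large enough that a private candidate CH variant (1 carrier) sits
    below the 0.25% carrier-ratio cutoff, so the recurrent-artifact
    filter behaves as it does at study scale.
    """
    return simulate_cohort(SimulationConfig(n_patients=1500, seed=11))
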