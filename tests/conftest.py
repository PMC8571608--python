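import numpy as np
import pytest

from informed_dispersal import ScenarioConfig, run_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def short_run():
    """A small but complete two-replicate scenario run, shared across
    reporting and engine round-trip tests."""
    cfg = ScenarioConfig(
        strategy="personal_public",
        process="accurate",
        m=0.01,
        evolve_emigration=True,
        years=60,
        replicates=2,
        seed=7,
        summary_every=20,
    )
    return run_scenario(cfg)
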