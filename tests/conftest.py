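import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mockamp import (
    SimConfig,
    dereplicate,
    mock_reference_set,
    packaged_members,
    simulate_run,
)


@pytest.fixture(scope="session")
def members_with_reported():
    """The bundled 20-member community and the published copies/ug estimates."""
    return packaged_members(with_reported=True)


@pytest.fixture(scope="session")
def members(members_with_reported):
    return members_with_reported[0]


@pytest.fixture(scope="session")
def mock_refs():
    """Synthetic mock references with the default primer-bias conditions."""
    return mock_reference_set(seed=11)


@pytest.fixture(scope="session")
def flat_refs():
    """Synthetic mock references with uniform amplification efficiency."""
    return mock_reference_set(seed=11, low_efficiency={})


@pytest.fixture(scope="session")
def noisefree_run(flat_refs):
    """Three error-free samples: every read is an exact template copy."""
    cfg = SimConfig(
        n_samples=3, depth=200, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        chimera_prob=0.0, noise_prob=0.0, seed=5,
    )
    return simulate_run(flat_refs, cfg)


@pytest.fixture(scope="session")
def noisy_run(mock_refs):
    """A small multi-sample run at the default artefact rates: heterogeneous
    substitution errors, indels, chimeras and a singleton-generating
    contaminant tail."""
    cfg = SimConfig(n_samples=4, depth=300, seed=7)
    return simulate_run(mock_refs, cfg)


@pytest.fixture(scope="session")
def noisy_table(noisy_run):
    return dereplicate(noisy_run.sequences_by_sample())
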