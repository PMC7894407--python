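import pytest

from phylloflux import synthetic


@pytest.fixture(scope="session")
def noisefree_replicate():
    """Single noise-free enclosure series with the default truth."""
    scenario = synthetic.EnclosureScenario(noise_cv=0.0, n_replicates=1, seed=7)
    return synthetic.gen_enclosure_series(scenario)[0], scenario


@pytest.fixture(scope="session")
def noisy_replicates():
    """Five replicates at the default instrument noise level."""
    scenario = synthetic.EnclosureScenario(noise_cv=0.02, n_replicates=5, seed=11)
    return synthetic.gen_enclosure_series(scenario), scenario


@pytest.fixture(scope="session")
def assay_grid():
    scenario = synthetic.AssayScenario(seed=3)
    return synthetic.gen_assay_traces(scenario), scenario
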