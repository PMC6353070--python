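import pytest

from metaproteo.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete PSM-level experiment shared across tests."""
    cfg = SimConfig(seed=11, n_proteins=300, n_species=12, depth_per_sample=6000)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    from metaproteo.simulate import write_fixture

    d = tmp_path_factory.mktemp("fixture")
    write_fixture(small_sim, d)
    return d
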