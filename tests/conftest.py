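import numpy as np
import pytest

from acylswath import (
    SimPeptideSpec,
    SimScenario,
    load_window_scheme,
    read_run,
    read_targets,
    simulate_run,
)


@pytest.fixture(scope="session")
def single_site_bundle(tmp_path_factory):
    """Noise-free single-peptide run, true occupancy 0.10, perfect reagent."""
    scenario = SimScenario(
        peptides=[SimPeptideSpec("GFKRIAE", (3,), (0.10,))],
        noise=0.0, purity=1.0, seed=11,
    )
    return simulate_run(scenario, tmp_path_factory.mktemp("single"))


@pytest.fixture(scope="session")
def two_site_bundle(tmp_path_factory):
    """Noise-free twin of a double-lysine peptide at (0.923, 0.016)."""
    scenario = SimScenario(
        peptides=[SimPeptideSpec("FCKAFNAKTDSIE", (3, 8), (0.923, 0.016))],
        noise=0.0, purity=1.0, seed=12,
    )
    return simulate_run(scenario, tmp_path_factory.mktemp("twosite"))


@pytest.fixture(scope="session")
def loaded_single(single_site_bundle):
    scheme = load_window_scheme(single_site_bundle.scheme_path)
    run = read_run(single_site_bundle.mzml_path, scheme)
    target = read_targets(single_site_bundle.targets_path)[0]
    return run, scheme, target


@pytest.fixture()
def rng():
    return np.random.default_rng(20160902)
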