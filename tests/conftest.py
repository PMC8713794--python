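"""Shared fixtures: a small simulated study and its derived catalog."""

import pytest

from preatlas.catalog import call_pres, normalize_signal
from preatlas.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study (seed 1, no RNA label noise)."""
    return simulate(SimulationConfig(seed=1, rna_label_noise=0.0))


@pytest.fixture(scope="session")
def catalog(dataset):
    ranked = normalize_signal(dataset.tf_peaks, dataset.tf_library_sizes)
    return call_pres(ranked)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """The same study written to disk, for I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("sim")
    simulate(SimulationConfig(seed=1, rna_label_noise=0.0), out_dir=out)
    return out
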