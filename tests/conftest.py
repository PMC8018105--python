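import pytest

from epirelapse.io_model import align_inputs
from epirelapse.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 2000-probe default cohort (45 patients, 5 subgroups), fixed seed."""
    return simulate_dataset(SimulationConfig(n_probes=2000, seed=11))


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    return align_inputs(
        small_dataset.annotation,
        small_dataset.beta,
        small_dataset.sheet,
        small_dataset.intensities,
    )
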