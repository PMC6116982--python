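import pytest

from ebcal import simulate as sim
from ebcal.models import MeasurementDataset, SMEMNSpec
from ebcal.samplers import ChainConfig, rjmcmc_fit


def small_generator(seed=7, n_per_component=12, n_replicates=4, **kwargs):
    """A scaled-down generator config (n = 5 * n_per_component subjects)."""
    counts = (n_per_component,) * 5
    return sim.default_config(
        seed=seed,
        n_subjects=5 * n_per_component,
        n_replicates=n_replicates,
        mixture=sim.MixtureSpec.calibrated(counts=counts),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_dataset():
    return sim.assemble_dataset(small_generator())


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size (n=300, J=4, normal errors) dataset."""
    return sim.assemble_dataset(sim.default_config(seed=11))


@pytest.fixture(scope="session")
def smemn_fit(default_dataset):
    """A short SMEMN fit on the default dataset, shared across tests."""
    ds = MeasurementDataset.from_simulated(default_dataset)
    config = ChainConfig(
        n_chains=1, n_iterations=2000, burn_in=600, seed=42, spline_thin=5
    )
    return rjmcmc_fit(SMEMNSpec(), ds, config)
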