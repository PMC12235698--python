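import numpy as np
import pytest

from pairnovo.spectra_io import Spectrum, build_token_dictionary
from pairnovo.synthetic_data import SimConfig, default_dictionary, generate_dataset


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def dictionary(sim_config):
    """Token dictionary over the 10-residue simulation alphabet."""
    return default_dictionary(sim_config)


@pytest.fixture(scope="session")
def full_dictionary():
    """Dictionary covering all 20 canonical residues."""
    from pairnovo.masses import MONOISOTOPIC

    return build_token_dictionary([[t] for t in MONOISOTOPIC])


@pytest.fixture(scope="session")
def small_dataset(sim_config):
    """Twenty corrupted synthetic spectra (default generator settings)."""
    return generate_dataset(20, sim_config)


@pytest.fixture()
def random_spectrum():
    rng = np.random.default_rng(7)
    n = 12
    return Spectrum(
        spectrum_id="random",
        mz=np.sort(rng.uniform(100, 1200, n)),
        intensity=rng.uniform(0.1, 10.0, n),
        precursor_mz=650.0,
        charge=2,
    )
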