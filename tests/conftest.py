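import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from riboqms.synthetic import (
    default_assembly_truth,
    default_proteome,
    simulate_proteome_spectra,
)


@pytest.fixture(scope="session")
def proteome():
    return default_proteome()


@pytest.fixture(scope="session")
def assembly_truth():
    return default_assembly_truth()


@pytest.fixture(scope="session")
def noiseless_spectra(assembly_truth, proteome):
    """(peaklists, designs, truth_table) at zero noise."""
    return simulate_proteome_spectra(assembly_truth, proteome, noise_sigma=0.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140905)
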