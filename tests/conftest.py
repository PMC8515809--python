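import numpy as np
import pytest

import ppiikit as pk


@pytest.fixture(scope="session")
def ppii_chain():
    """18-residue ideal polyproline II backbone."""
    return pk.build_ideal_chain(18, -75.0, 145.0, 180.0)


@pytest.fixture(scope="session")
def ppi_chain():
    """18-residue ideal polyproline I backbone (cis peptide bonds)."""
    return pk.build_ideal_chain(18, -75.0, 160.0, 0.0)


@pytest.fixture(scope="session")
def mixed_ensemble():
    """13-mer with 0.7 PPII / 0.3 beta weights at every residue, 2000 frames."""
    profile = pk.uniform_profile("A" * 13, {"PPII": 0.7, "beta": 0.3})
    return pk.sample_ensemble(pk.SyntheticSpec(profile, n_frames=2000, seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
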