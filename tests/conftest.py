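import numpy as np
import pytest

from paeseg import Architecture, Element, generate_pae


@pytest.fixture(scope="session")
def two_domain():
    """Clean two-domain protein (150 + 8-linker + 120) with its ground truth."""
    arch = Architecture(
        (Element("domain", 150), Element("linker", 8), Element("domain", 120)),
        rng_seed=7,
    )
    return generate_pae(arch, noise_sd=0.5)


@pytest.fixture(scope="session")
def disordered_n_protein():
    """One domain preceded by a 40-residue disordered N-terminus, noiseless."""
    arch = Architecture(
        (Element("disordered_n", 40), Element("domain", 200)), rng_seed=3
    )
    return generate_pae(arch, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
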