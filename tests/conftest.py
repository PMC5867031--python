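import numpy as np
import pytest

from famedit.synthetic import EditProfile, FamilyConfig, generate_family


@pytest.fixture(scope="session")
def small_family():
    """A 20-gene family at 2% divergence used by several test modules."""
    cfg = FamilyConfig(n_genes=20, snp_rate=0.02, pseudogene_fraction=0.3, rng_seed=101)
    return generate_family(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
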