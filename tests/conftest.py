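import numpy as np
import pytest

from pmhcforge.docking import ProtocolConfig
from pmhcforge.fixtures import FixtureSpec, make_toy_cleft


@pytest.fixture(scope="session")
def toy_cleft():
    """Default planted-truth complex: KAVYNFATM in a plain groove."""
    return make_toy_cleft(FixtureSpec())


@pytest.fixture(scope="session")
def toy_cleft_pocket():
    """Same groove with a deep p5 pocket."""
    return make_toy_cleft(FixtureSpec(pocket_depths={5: 3.0}))


@pytest.fixture(scope="session")
def poly_ala_cleft():
    """All-neutral fixture: polyalanine peptide in a neutral groove."""
    return make_toy_cleft(FixtureSpec(peptide_seq="AAAAAAAAA"))


@pytest.fixture
def small_config():
    """Scaled-down protocol for desk-speed docking runs."""
    return ProtocolConfig(n_runs=3, n_out_per_run=12, iterations=20,
                          em_short=40, em_long=120, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
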