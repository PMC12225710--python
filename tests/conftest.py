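import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from stairbayes import PriorFamily, PriorSpec, SiteFrequencySpectrum
from stairbayes.scenarios import scenario, scenario_to_theta, simulate_sfs


@pytest.fixture(scope="session")
def constant_sfs():
    """A spectrum simulated from the constant-size history (N=1e4, n=20,
    l=1e6, mu=1.2e-8) with its generating theta."""
    scn = scenario("constant")
    theta = scenario_to_theta(scn)
    sfs = simulate_sfs(theta, scn.l, seed=1234)
    return sfs, theta, scn


@pytest.fixture
def toy_sfs():
    return SiteFrequencySpectrum(n=4, counts=(6, 3, 1), monomorphic_count=90)


@pytest.fixture
def zero_sfs():
    return SiteFrequencySpectrum(n=6, counts=(0,) * 5, monomorphic_count=0)


@pytest.fixture
def gmrf_spec():
    return PriorSpec(PriorFamily.GMRF1)
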