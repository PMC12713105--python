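import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breakscape.dsb import BinnedTrack, dsb_ratio
from breakscape.genome import make_bins
from breakscape.simulate import SimulationParams, simulate_all

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic study at the default conditions, seed 7."""
    return simulate_all(SimulationParams(seed=7), with_contacts=False)


@pytest.fixture(scope="session")
def default_ratio(default_sim):
    return dsb_ratio(default_sim.treated_dsb, default_sim.control_dsb)


@pytest.fixture
def toy_binning():
    """Two short chromosomes on 5 kb bins (chr1: 20 bins, chr2: 10 bins)."""
    return make_bins({"chr1": 100_000, "chr2": 50_000}, 5000)


def make_track(binning, values):
    return BinnedTrack(binning, np.asarray(values, dtype=float))
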