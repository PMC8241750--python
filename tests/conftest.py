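"""Shared fixtures: small phantoms and a miniature MR acquisition chain.

Session-scoped so the expensive simulation/reconstruction objects are
built once and reused read-only across tests.
"""

import pytest

from crmoco import mr_recon, mr_sim
from crmoco import phantom as ph


@pytest.fixture(scope="session")
def desk_config():
    """64x64 at 2 mm, short scan: the default desk-scale study conditions."""
    return ph.PhantomConfig(grid_shape=(64, 64), pixel_size=2.0,
                            duration=240.0, mr_window=120.0, seed=0)


@pytest.fixture(scope="session")
def desk_phantom(desk_config):
    return ph.build_phantom(desk_config)


@pytest.fixture(scope="session")
def desk_surrogates(desk_config):
    return ph.generate_surrogates(desk_config)


@pytest.fixture(scope="session")
def static_config():
    """Motion-free phantom for encoding/reconstruction oracles."""
    return ph.PhantomConfig(grid_shape=(32, 32), pixel_size=3.0,
                            resp_amplitude=0.0, cardiac_contraction_fraction=0.0,
                            duration=120.0, mr_window=60.0, seed=0)


@pytest.fixture(scope="session")
def static_phantom(static_config):
    return ph.build_phantom(static_config)


@pytest.fixture(scope="session")
def static_surrogates(static_config):
    return ph.generate_surrogates(static_config)


@pytest.fixture(scope="session")
def full_sampled_kspace(static_phantom, static_surrogates):
    """Noiseless, fully sampled (corner-covering) acquisition of the
    static phantom."""
    cfg = mr_sim.MRSequenceConfig(spokes_total=80, samples_per_spoke=80, noise_sd=0.0)
    traj = mr_sim.make_trajectory(cfg, static_surrogates.mr_window,
                                  static_phantom.pixel_size)
    ks = mr_sim.simulate_acquisition(static_phantom, static_surrogates, cfg, traj)
    return ks


@pytest.fixture(scope="session")
def single_bin(full_sampled_kspace, static_surrogates):
    return mr_recon.bin_kspace(full_sampled_kspace, static_surrogates,
                               mr_recon.BinningSpec(n_resp=1, n_card=1),
                               "respiratory")
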