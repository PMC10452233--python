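import numpy as np
import pytest

from pecnet.synthetic import SimulationConfig, generate_source_signals


@pytest.fixture(scope="session")
def coupled_pair_factory():
    """Generate a 2-ROI source pair with a planted latent envelope
    correlation; returns (sources, ground_truth)."""

    def make(rho: float, seed: int, duration: float = 60.0,
             dipole_noise: float = 0.0, **kw):
        cfg = SimulationConfig(n_rois=2, dipoles_per_roi=1, n_sensors=4,
                               band=(13.0, 30.0),
                               coupling_spec=((0, 1, rho),),
                               dipole_noise=dipole_noise, **kw)
        src, gt, _ = generate_source_signals(cfg, seed, duration=duration)
        return src, gt

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
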