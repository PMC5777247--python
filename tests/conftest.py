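import sys
from pathlib import Path

import numpy as np
import pytest

# make the sibling oracle module importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))

from tightrope.simulate import TrajectorySimConfig, simulate_free_diffusion


@pytest.fixture
def free_config():
    """Study-condition free-diffusion config, far from the boundaries."""
    return TrajectorySimConfig(
        D_free=0.1, frame_interval_s=0.05, n_frames=500,
        localization_sigma_um=0.016, tightrope_length_um=40.0,
        start_position_um=20.0, seed=0,
    )


@pytest.fixture
def random_gappy_trajectory():
    """Factory for short random traces with absent frames, for oracle checks."""
    def make(seed, n=50, p_absent=0.15):
        rng = np.random.default_rng(seed)
        cfg = TrajectorySimConfig(
            D_free=0.05, frame_interval_s=0.1, n_frames=n,
            localization_sigma_um=0.01, tightrope_length_um=10.0,
            start_position_um=5.0, seed=seed,
        )
        traj = simulate_free_diffusion(cfg)
        absent = rng.random(n) < p_absent
        absent[0] = False
        traj.present = traj.present & ~absent
        traj.positions_um = np.where(traj.present, traj.positions_um, np.nan)
        return traj
    return make
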