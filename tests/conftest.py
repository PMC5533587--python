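import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from slbkin.synthetic_trajectories import ImagingConfig, Trajectory, TrajectorySet


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_trajectory(traj_id, start_frame, n_frames, mode="Dynamic", censored=False,
                    positions=None, intensity=None, rng=None):
    """Hand-built trajectory with diffusive positions unless overridden."""
    if positions is None:
        if rng is None:
            rng = np.random.default_rng(traj_id)
        steps = rng.normal(0.0, 0.2, size=(n_frames, 2))
        positions = np.cumsum(steps, axis=0)
    if intensity is None:
        intensity = np.ones(n_frames)
    return Trajectory(
        traj_id=traj_id,
        start_frame=start_frame,
        n_bound_frames=n_frames,
        positions=np.asarray(positions, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        mode_truth=mode,
        censored=censored,
    )


def make_set(specs, n_frames=50, dt=0.02, seed=0):
    """TrajectorySet from (start_frame, n_bound_frames) pairs."""
    cfg = ImagingConfig(seed=seed, dt=dt, n_frames=n_frames)
    trajs = [make_trajectory(i, s, L) for i, (s, L) in enumerate(specs)]
    return TrajectorySet(trajs, cfg)
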