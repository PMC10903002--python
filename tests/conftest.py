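import numpy as np
import pytest

from progdelay import (
    TrajectorySpec,
    TreatmentEffectSpec,
    default_trajectory,
    generate_trial,
)


@pytest.fixture(scope="session")
def traj():
    return default_trajectory()


@pytest.fixture(scope="session")
def effect20():
    return TreatmentEffectSpec(slowing_fraction=0.20)


@pytest.fixture(scope="session")
def noisy_trial(traj, effect20):
    """One moderately sized noisy trial reused across fitting tests."""
    return generate_trial(traj, effect20, n_per_arm=150, duration_months=36, seed=7)


@pytest.fixture(scope="session")
def linear_traj():
    """Trajectory whose mean is exactly linear in time (slope 0.05/month)."""
    months = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0)
    means = tuple(1.5 + 0.05 * m for m in months)
    return TrajectorySpec(months, means, np.zeros((6, 6)))


@pytest.fixture(scope="session")
def convex_toy_traj():
    """Small convex trajectory used for hand-computed interpolation values."""
    return TrajectorySpec(
        (0.0, 12.0, 24.0, 36.0), (0.0, 0.3, 1.0, 2.2), np.zeros((4, 4))
    )
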