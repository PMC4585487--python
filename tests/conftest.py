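import math

import numpy as np
import pytest
from hypothesis import settings

import tonocore as tc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def paper_schedule():
    """The printed human design: 8 tones x 20 reps, 2-trial epochs, 4 dummies."""
    return tc.make_schedule(8, 20, 2, 4, 2, seed=101)


@pytest.fixture(scope="session")
def mirror_layout():
    return tc.make_field_layout((20, 20))


@pytest.fixture(scope="session")
def noiseless_series(mirror_layout, paper_schedule):
    return tc.simulate_experiment(mirror_layout, None, paper_schedule,
                                  noise_sd=0.0, jitter_semitones=0.0,
                                  seed=5, n_z=1)


@pytest.fixture(scope="session")
def noisy_series(mirror_layout, paper_schedule):
    return tc.simulate_experiment(mirror_layout, None, paper_schedule,
                                  noise_sd=1.0, seed=6, n_z=1)


def mirror_wedge(alpha_deg: float, n: int = 31, slope: float = 0.2) -> np.ndarray:
    """Analytic wedge phantom: two half-plane gradients meeting at the centre
    column with inter-gradient angle ``alpha_deg``; the crease sits exactly on
    the centre column (angles < 180 need a shared along-border component)."""
    b1 = math.radians((180.0 - alpha_deg) / 2.0)
    a, b = math.cos(b1), math.sin(b1)
    x = np.arange(n) - n // 2
    y = (np.arange(n) - n // 2)[:, None]
    return slope * (a * np.abs(x)[None, :] + b * y)


def tilted_mirror(phi_deg: float, n: int = 31, offset: float = 0.5001,
                  slope: float = 0.2) -> np.ndarray:
    """Pure mirror reversal (180 deg) with gradient axis at ``phi_deg``; the
    crease runs between lattice columns for phi = 0."""
    x = (np.arange(n) - n // 2)[None, :]
    y = (np.arange(n) - n // 2)[:, None]
    u = x * math.cos(math.radians(phi_deg)) + \
        y * math.sin(math.radians(phi_deg)) + offset
    return slope * np.abs(u)
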