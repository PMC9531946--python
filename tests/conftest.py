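import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import papa_spt as p


@pytest.fixture(scope="session")
def standard_protocol():
    """The canonical 10-cycle SPT protocol with single-frame pulses."""
    return p.parse_protocol(
        "10 cycles of 250 R [2 ms], 1 V [7 ms], 500 R [2 ms], "
        "1 G [7 ms], 250 R [2 ms]"
    )


@pytest.fixture(scope="session")
def quiet_photophysics():
    """All rates zero: molecules stay bright forever."""
    return p.PhotophysicsModel(
        p_shelve_per_ms_red=0.0,
        p_bleach_per_ms_red=0.0,
        shelvable_fraction=1.0,
        k_dr_per_ms_violet=0.0,
        k_papa_per_ms_green=0.0,
        k_papa_background_per_ms_green=0.0,
        p_spont_per_frame=0.0,
        p_sender_bleach_per_ms_green=0.0,
    )


@pytest.fixture(scope="session")
def bound_free_trajectories():
    """2000 two-state trajectories, 70% bound, shared across tests."""
    motion = p.MotionModel(d_bound=0.01, d_free=8.3, f_bound=0.70)
    return p.simulate_two_state_trajectories(
        2000, motion, seed=101, mean_track_length=8.0
    )
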