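import numpy as np
import pytest

from hsafm_spt import SimConfig, TiltDynamics, render_movie, simulate_trajectories

# field large enough that reflecting boundaries never fire: free-Brownian
# closed forms then apply exactly
BIG_FIELD_NM = 1.0e9


def free_config(**kwargs) -> SimConfig:
    """SimConfig for estimator-only tests: effectively unbounded field."""
    kwargs.setdefault("field_size_nm", BIG_FIELD_NM)
    kwargs.setdefault("n_pixels", 16)
    return SimConfig(**kwargs)


def fixed_tilt(theta_deg: float) -> TiltDynamics:
    """Degenerate tilt dynamics pinning the tilt to a constant angle."""
    return TiltDynamics(theta_min_deg=theta_deg, theta_max_deg=theta_deg,
                        relaxation_time_s=1.0, theta_sd_deg=0.0)


@pytest.fixture(scope="session")
def small_movie():
    """60-frame default-conditions movie with one particle, plus its truth."""
    cfg = SimConfig(n_frames=60, n_particles=1, seed=11)
    truth = simulate_trajectories(cfg)
    return truth, render_movie(truth, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
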