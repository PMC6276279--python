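import numpy as np
import pytest

from credkit.schedule import build_schedule
from credkit.synthetic import SyntheticExperiment, simulate_rotation_series


@pytest.fixture(scope="session")
def drifting_series():
    """Simulated cRED series whose crystal drifts out of the aperture.

    30 data frames, defocus every 10; linear drift chosen so the
    aperture-overlap attenuation falls from 1 toward ~0.2 over the run.
    """
    schedule = build_schedule(n_data=30, n_interval=10, frame_time=0.512,
                              start_angle=-5.0, rotation_speed=1.0)
    exp = SyntheticExperiment(
        seed=42,
        drift_per_slot=(0.028, 0.0),   # um per slot
        aperture_radius=0.75,
        crystal_radius=0.35,
        beam_center=(258.0, 255.0),
    )
    frames, truth = simulate_rotation_series(exp, schedule)
    return {"schedule": schedule, "exp": exp, "frames": frames, "truth": truth}


@pytest.fixture(scope="session")
def steady_series():
    """Simulated series with no drift: attenuation identically 1."""
    schedule = build_schedule(n_data=24, n_interval=10, frame_time=0.512,
                              start_angle=0.0, rotation_speed=1.2)
    exp = SyntheticExperiment(seed=7, beam_center=(260.0, 254.0))
    frames, truth = simulate_rotation_series(exp, schedule)
    return {"schedule": schedule, "exp": exp, "frames": frames, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
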