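import numpy as np
import pandas as pd
import pytest

from gaitxpop import synthetic


@pytest.fixture(scope="session")
def quiet_profile():
    """Small, nearly noise-free single-speed population."""
    return synthetic.PopulationProfile(
        name="young", n_participants=5, cadence_mean=112.0, cadence_sd=5.0,
        sensor_noise_sd=0.01, phase_jitter_sd=0.005,
        bout_duration_dist=(20.0, 25.0), n_speed_conditions=1,
        heterogeneity_scale=1.0)


@pytest.fixture(scope="session")
def quiet_recording(quiet_profile):
    spec = synthetic.sample_population(quiet_profile, seed=1)[0]
    return synthetic.generate_recording(spec, seed=7)


@pytest.fixture(scope="session")
def tiny_windows(quiet_profile):
    """Windowed dataset over five short, clean recordings."""
    from gaitxpop.preprocessing import preprocess_recording
    from gaitxpop.windowing import WindowConfig, windows_from_recordings

    specs = synthetic.sample_population(quiet_profile, seed=1)
    recs = [synthetic.generate_recording(s, seed=50 + i)
            for i, s in enumerate(specs)]
    cleaned = [preprocess_recording(r)[0] for r in recs]
    return windows_from_recordings(cleaned, WindowConfig())


@pytest.fixture(scope="session")
def tiny_manifest(quiet_profile):
    specs = synthetic.sample_population(quiet_profile, seed=1)
    return pd.DataFrame({
        "participant_id": [s.participant_id for s in specs],
        "group": [s.group for s in specs]})
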