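import numpy as np
import pandas as pd
import pytest

from fcdecode import (TuningSpec, ball_coords, generate_trial_sequence,
                      generate_voxel_population, simulate_betas,
                      simulate_reports)


@pytest.fixture(scope="session")
def session_trials():
    """A full synthetic session: 10 runs, 16 trials per coherence per run."""
    trials = generate_trial_sequence(n_runs=10, trials_per_coherence=16, seed=11)
    return simulate_reports(trials, seed=12)


@pytest.fixture(scope="session")
def cluster_voxels():
    """Searchlight-sized informative cluster on a radius-4 lattice ball."""
    coords = ball_coords(4.0)
    return generate_voxel_population(
        coords.shape[0], coords=coords,
        tuning_spec=TuningSpec(noise_sd=0.2), seed=13)


@pytest.fixture(scope="session")
def cluster_betas(session_trials, cluster_voxels):
    return simulate_betas(session_trials, cluster_voxels, seed=14)


def make_fixed_direction_trials(theta: float, n: int, coherence: str = "full",
                                level: float = 1.0) -> pd.DataFrame:
    """Minimal trial table with one repeated stimulus direction."""
    return pd.DataFrame({
        "trial_id": np.arange(n), "run": 1, "coherence": coherence,
        "coherence_level": level, "bin_index": 1, "theta_s": theta,
        "theta_r": np.nan, "onset": np.arange(n) * 12.0 + 0.5, "duration": 2.0,
        "iti": 3.0, "valid": True,
    })
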