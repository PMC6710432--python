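import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pdpattern.phantom import (
    EffectSchedule,
    build_phantom_atlas,
    default_region_effects,
    generate_cohort,
    make_ground_truth_pattern,
)
from pdpattern.preprocess import DataMatrix, build_data_matrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas():
    """Compact 20^3 phantom with 6 parcels, for fast unit tests."""
    atlas, mask = build_phantom_atlas((20, 20, 20), 6, seed=3)
    return atlas, mask


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """Strong-signal small cohort (5 PD / 4 controls, 2 timepoints)."""
    atlas, mask = small_atlas
    effects = {1: 0.15, 2: 0.15, 3: -0.15, 4: -0.15}
    truth, truth_vec = make_ground_truth_pattern(atlas, effects)
    scans = generate_cohort(
        atlas, truth, n_pd=5, n_control=4,
        schedule=EffectSchedule({"baseline": 0.0, "w9": 1.0}),
        voxel_noise_sd=2.0, seed=11, timepoints=("baseline", "w9"), mask=mask,
    )
    return atlas, mask, truth, truth_vec, scans


@pytest.fixture(scope="session")
def small_w9(small_cohort):
    atlas, mask, truth, truth_vec, scans = small_cohort
    dm = build_data_matrix([s for s in scans if s.timepoint == "w9"], mask, fwhm=1.6)
    return dm


def make_matrix(X, groups=None, motor=None) -> DataMatrix:
    """Wrap a plain array as a DataMatrix with minimal metadata."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if groups is None:
        groups = ["PD"] * (n // 2) + ["control"] * (n - n // 2)
    meta = pd.DataFrame(
        {
            "subject_id": [f"s{i:02d}" for i in range(n)],
            "group": groups,
            "timepoint": ["w9"] * n,
            "motor_score": motor if motor is not None else np.zeros(n),
        }
    )
    return DataMatrix(X=X, mask_index=np.zeros((X.shape[1], 3), int), meta=meta)
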