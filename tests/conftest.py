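import numpy as np
import pandas as pd
import pytest

from netseg import CohortSpec, default_parcellation


@pytest.fixture(scope="session")
def parc300():
    return default_parcellation()


@pytest.fixture()
def small_parc():
    """Reduced parcellation: 4 analysis networks x 5 ROIs + 2 unassigned."""
    rows = []
    i = 0
    for net in ("NetA", "NetB", "NetC", "NetD"):
        for _ in range(5):
            i += 1
            rows.append((f"ROI{i:03d}", net))
    for _ in range(2):
        i += 1
        rows.append((f"ROI{i:03d}", "Unassigned"))
    return pd.DataFrame(rows, columns=["roi_id", "network"])


@pytest.fixture()
def small_spec():
    """Fast cohort spec used by the small end-to-end tests."""
    return CohortSpec(
        n_subjects=4,
        n_frames_per_run=150,
        n_runs=2,
        within_z={"NetA": 0.5, "NetB": 0.5, "NetC": 0.4, "NetD": 0.6},
        frames_floor=200,
        seed=7,
        planted_beta_seg={"NetA": 0.35},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
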