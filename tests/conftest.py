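import numpy as np
import pandas as pd
import pytest

import equispeed as eq
from equispeed.preprocess import extract_cohort_windows


@pytest.fixture(scope="session")
def small_cohort():
    """Three subjects, five gaits, 12 s per gait: the shared test cohort."""
    return eq.simulate_cohort(
        3, schedule_template=eq.default_schedule(12.0), seed=42)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    return extract_cohort_windows(small_cohort)


@pytest.fixture(scope="session")
def small_matrix_lh(small_windows):
    """Feature matrix of the LH singleton set (138 feature columns)."""
    return eq.build_feature_matrix(small_windows, "LH")


@pytest.fixture(scope="session")
def random_windows():
    """100 seeded random 256-sample windows for oracle comparisons."""
    rng = np.random.default_rng(7)
    return rng.normal(0.0, 1.0, size=(100, 256))


def make_selection_problem(seed: int, n_subjects: int = 6, n_per: int = 25,
                           n_noise: int = 4) -> pd.DataFrame:
    """Six-feature regression problem: one strong predictor, one weak,
    the rest pure noise; grouped by synthetic subject."""
    rng = np.random.default_rng(seed)
    parts = []
    for s in range(n_subjects):
        v = rng.uniform(1.0, 8.0, n_per)
        df = pd.DataFrame(rng.normal(0.0, 1.0, (n_per, n_noise)),
                          columns=[f"noise{i}" for i in range(n_noise)])
        df["strong"] = v + rng.normal(0.0, 0.2, n_per)
        df["weak"] = 0.5 * v + rng.normal(0.0, 1.0, n_per)
        df["speed"] = v
        df["subject"] = f"S{s}"
        df["gait"] = "walk"
        df["breed"] = "x"
        df["window_id"] = np.arange(n_per)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
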