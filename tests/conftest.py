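import numpy as np
import pandas as pd
import pytest

from glucowear import generate_cohort
from glucowear.features import FeatureMatrix, PID_COL, TARGET_COL, TIME_COL
from glucowear.scenarios import mini_cohort_config
from glucowear.types import SensorStream


@pytest.fixture(scope="session")
def mini_records():
    """Small two-participant cohort with MMT annotations."""
    return generate_cohort(mini_cohort_config(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_stream(values, rate=4.0, t0=1_600_000_000.0, modality="EDA"):
    values = np.asarray(values, dtype=float)
    return SensorStream(
        modality=modality, native_rate=rate,
        timestamps=t0 + np.arange(values.size) / rate, values=values,
    )


def make_matrix(X, names, target, groups=None, t0=0.0):
    """Wrap a plain design matrix into a FeatureMatrix for model tests."""
    X = np.asarray(X, dtype=float)
    frame = pd.DataFrame(X, columns=names)
    n = X.shape[0]
    if groups is None:
        groups = np.repeat([f"Q{i}" for i in range(5)], int(np.ceil(n / 5)))[:n]
    frame[PID_COL] = groups
    frame[TIME_COL] = t0 + 300.0 * np.arange(n)
    frame[TARGET_COL] = np.asarray(target, dtype=float)
    return FeatureMatrix(frame=frame, feature_names=list(names))
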