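import numpy as np
import pandas as pd
import pytest

from icuglyc.records import DesignMatrix, assemble_design
from icuglyc.synthetic import PatientProfile, SimConfig, simulate_patient


@pytest.fixture(scope="session")
def profile():
    return PatientProfile("p01", "trauma", 50.0, 30.0, False, 5.0)


@pytest.fixture(scope="session")
def default_patient(profile):
    """One 24-hour patient under default simulator conditions."""
    cfg = SimConfig(seed=3, duration_hours=24.0)
    return simulate_patient(profile, cfg)


@pytest.fixture(scope="session")
def default_design(default_patient):
    _, cgm, records = default_patient
    return assemble_design(cgm, records)


def make_design(X, Y, start="2013-03-04T00:00"):
    """Wrap raw arrays as a DesignMatrix for model-level tests."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(X)
    idx = pd.date_range(start, periods=n, freq="5min")
    Xdf = pd.DataFrame(X, index=idx, columns=[f"x{i}" for i in range(X.shape[1])])
    Ydf = pd.DataFrame(Y, index=idx,
                       columns=[f"target_{5 * (k + 1)}" for k in range(Y.shape[1])])
    return DesignMatrix(idx, Xdf, Ydf, np.array(["normo"] * n), 5.0,
                        5.0 * Y.shape[1])
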