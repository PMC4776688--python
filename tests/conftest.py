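import numpy as np
import pytest

from actihr.preprocessing import RegularSeries
from actihr.synthetic import AcquisitionModel, load_profiles


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def clean_acq():
    return AcquisitionModel(dropout_rate=0.0, artifact_rate=0.0, record_days=14)


def regular(values, interval=10.0, start=0.0, kind="hr"):
    return RegularSeries(kind=kind, start=start, interval=interval,
                         values=np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def separable_features():
    """A linearly separable two-cluster feature matrix (12 cases / 19 controls)."""
    import pandas as pd

    rng = np.random.default_rng(42)
    n_case, n_ctrl, d = 12, 19, 4
    case = rng.normal(3.0, 0.3, size=(n_case, d))
    ctrl = rng.normal(-3.0, 0.3, size=(n_ctrl, d))
    X = pd.DataFrame(np.vstack([case, ctrl]), columns=[f"f{i}" for i in range(d)])
    y = np.array([1] * n_case + [0] * n_ctrl)
    return X, y
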