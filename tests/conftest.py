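import numpy as np
import pandas as pd
import pytest

from convergekit import CallFeatureTable, build_structure


def make_feature_table(X: np.ndarray, labels, call_ids=None) -> CallFeatureTable:
    """Wrap a raw matrix + labels into a CallFeatureTable."""
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(X.shape[1])])
    df.insert(0, "individual_id", list(labels))
    if call_ids is None:
        call_ids = [f"c{i}" for i in range(len(df))]
    df.insert(0, "call_id", list(call_ids))
    return CallFeatureTable(df)


@pytest.fixture
def study_structure():
    """The emulated population: 2 gangs x 2 parties (6, 7, 5, 9 males)."""
    return build_structure([[6, 7], [5, 9]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


try:
    from hypothesis import settings

    settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass
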