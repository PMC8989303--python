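import numpy as np
import pandas as pd
import pytest

from stablecv.core_data import CATEGORICAL, NUMERIC, FeatureTable


def make_table(X: np.ndarray, y: np.ndarray, prefix: str = "x") -> FeatureTable:
    """Numeric-only FeatureTable from arrays."""
    cols = [f"{prefix}{j + 1}" for j in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols,
                         index=pd.Index([f"P{i:03d}" for i in range(len(X))],
                                        name="patient_id"))
    return FeatureTable(frame=frame, kinds={c: NUMERIC for c in cols},
                        target=pd.Series(y, index=frame.index))


@pytest.fixture
def balanced_table() -> FeatureTable:
    """20 patients, 10/10 classes, one informative + one null feature."""
    rng = np.random.default_rng(7)
    y = np.array([0, 1] * 10)
    X = np.column_stack([y * 2.0 + rng.normal(0, 0.3, 20),
                         rng.normal(0, 1, 20)])
    return make_table(X, y)


@pytest.fixture
def separable_table() -> FeatureTable:
    """60 patients with one near-perfectly separating feature."""
    rng = np.random.default_rng(11)
    y = np.array([0, 1] * 30)
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, 60),
                         rng.normal(0, 1, 60),
                         rng.normal(0, 1, 60)])
    return make_table(X, y)


@pytest.fixture
def mixed_table() -> FeatureTable:
    """Mixed numeric/categorical table with a missing cell."""
    rng = np.random.default_rng(3)
    n = 40
    y = np.array([0, 1] * 20)
    frame = pd.DataFrame({
        "age": rng.normal(50, 10, n),
        "severity": rng.choice(["A", "B", "C"], n),
        "marker": y * 1.5 + rng.normal(0, 0.5, n),
    }, index=pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id"))
    frame.loc["P003", "age"] = np.nan
    frame.loc["P005", "severity"] = np.nan
    return FeatureTable(
        frame=frame,
        kinds={"age": NUMERIC, "severity": CATEGORICAL, "marker": NUMERIC},
        target=pd.Series(y, index=frame.index))
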