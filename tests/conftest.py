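import numpy as np
import pytest

from ttsurv.data import SurvivalDataset
from ttsurv.schema import Feature, FeatureSchema


@pytest.fixture
def tiny_schema() -> FeatureSchema:
    """One continuous + two categorical covariates."""
    return FeatureSchema(
        features=(
            Feature("age", "continuous"),
            Feature("stage", "categorical", ("I", "II", "III", "IV")),
            Feature("sex", "categorical", ("F", "M")),
        ),
        duration_column="duration_days",
        event_column="event",
    )


@pytest.fixture
def tiny_data(tiny_schema) -> SurvivalDataset:
    rng = np.random.default_rng(7)
    n = 12
    return SurvivalDataset(
        schema=tiny_schema,
        x_cont=rng.normal(60, 10, (n, 1)),
        x_cat=np.column_stack([rng.integers(0, 4, n), rng.integers(0, 2, n)]),
        t=rng.uniform(10, 2000, n),
        d=np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0]),
        ids=np.array([f"P{i:03d}" for i in range(n)]),
    )


def finite_difference_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g
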