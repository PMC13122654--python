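import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from quadromics.containers import ExpressionMatrix

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_groups(n_per_group: int = 6) -> pd.Series:
    samples = [f"GRA_{i+1}" for i in range(n_per_group)] + [
        f"SUP_{i+1}" for i in range(n_per_group)
    ]
    return pd.Series(
        ["GRA"] * n_per_group + ["SUP"] * n_per_group, index=samples, name="group"
    )


def make_matrix(rows: dict, layer: str, n_per_group: int = 6) -> ExpressionMatrix:
    """Build an ExpressionMatrix from gene -> per-sample values."""
    groups = make_groups(n_per_group)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=groups.index, dtype=float)
    values.index.name = "gene"
    return ExpressionMatrix(values=values, groups=groups, layer=layer)


@pytest.fixture
def groups6() -> pd.Series:
    return make_groups(6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
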