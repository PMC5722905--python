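import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exranges as ex

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_series_expr() -> ex.ExpressionMatrix:
    """3 genes x (4 + 3) samples over two non-cyclic series."""
    rng = np.random.default_rng(7)
    samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(3)]
    values = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(3, 7)),
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    design = pd.DataFrame(
        {
            "series_id": ["A"] * 4 + ["B"] * 3,
            "time": [0.0, 2.0, 4.0, 6.0, 0.0, 2.0, 4.0],
        },
        index=samples,
    )
    return ex.ExpressionMatrix(values, design)


@pytest.fixture
def cyclic_expr() -> ex.ExpressionMatrix:
    """2 genes x 2 cyclic series of 6 samples each (even 2 h grid)."""
    rng = np.random.default_rng(11)
    samples = [f"{s}{i}" for s in "AB" for i in range(6)]
    values = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(2, 12)), index=["g1", "g2"], columns=samples
    )
    design = pd.DataFrame(
        {
            "series_id": ["A"] * 6 + ["B"] * 6,
            "time": list(np.arange(6) * 2.0) * 2,
            "cyclic": True,
        },
        index=samples,
    )
    return ex.ExpressionMatrix(values, design)


def random_expression(rng, n_genes, series_lengths, cyclic=False) -> ex.ExpressionMatrix:
    """Random valid expression matrix over the given series lengths."""
    samples, series, times = [], [], []
    for s, n in enumerate(series_lengths):
        t = np.sort(rng.choice(np.arange(100), size=n, replace=False)).astype(float)
        for i in range(n):
            samples.append(f"S{s}_{i}")
            series.append(f"S{s}")
            times.append(t[i])
    values = pd.DataFrame(
        rng.uniform(0.0, 50.0, size=(n_genes, len(samples))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    design = pd.DataFrame(
        {"series_id": series, "time": times, "cyclic": cyclic}, index=samples
    )
    return ex.ExpressionMatrix(values, design)
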