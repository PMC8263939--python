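import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_expr():
    """4 features x 4 samples, two groups, no structure."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(8, 1, (4, 4)),
        index=[f"g{i}" for i in range(4)],
        columns=["s1", "s2", "s3", "s4"],
    )


def make_sheet(samples, dataset="D1", groups=None):
    if groups is None:
        half = len(samples) // 2
        groups = ["normal"] * half + ["primary"] * (len(samples) - half)
    return pd.DataFrame({"sample": list(samples), "dataset": dataset,
                         "group": groups})


@pytest.fixture
def sheet_factory():
    return make_sheet


def two_group_expr(seed, n_genes=200, n_per_group=5, effect=None, sd=0.5,
                   groups=("metastatic", "normal")):
    """Random two-group matrix; ``effect`` plants shifts in the first genes."""
    rng = np.random.default_rng(seed)
    cols = [f"{g[0].upper()}{i}" for g in groups for i in range(n_per_group)]
    base = rng.normal(8, 1, n_genes)
    x = base[:, None] + rng.normal(0, sd, (n_genes, 2 * n_per_group))
    truth = np.zeros(n_genes, dtype=bool)
    if effect:
        n_de, size = effect
        signs = rng.choice([-1.0, 1.0], n_de)
        x[:n_de, :n_per_group] += signs[:, None] * size
        truth[:n_de] = True
    expr = pd.DataFrame(x, index=[f"g{i:04d}" for i in range(n_genes)],
                        columns=cols)
    sheet = pd.DataFrame({
        "sample": cols, "dataset": "D1",
        "group": [groups[0]] * n_per_group + [groups[1]] * n_per_group})
    return expr, sheet, truth
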