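import numpy as np
import pandas as pd
import pytest

from mrgradient import ExpressionMatrix, SurvivalTable, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact ground-truth cohort shared by read-only tests."""
    return simulate_cohort(
        n_samples=80, n_genes=400, n_tfs=12, targets_per_tf=15,
        n_cpgs=120, seed=3,
    )


@pytest.fixture()
def toy_expr():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(5)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 1, size=(6, 5)), index=genes, columns=samples)
    )


@pytest.fixture()
def toy_surv():
    return SurvivalTable(pd.DataFrame({
        "sample": [f"s{j}" for j in range(5)],
        "time": [3.0, 1.0, 4.0, 2.0, 5.0],
        "event": [1, 1, 0, 1, 0],
    }))
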