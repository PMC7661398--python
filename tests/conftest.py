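import numpy as np
import pandas as pd
import pytest

import txefficacy as tx


@pytest.fixture
def tiny_matrix() -> tx.ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["GA", "GB"], columns=["S1", "S2"]
    )
    return tx.ExpressionMatrix(values)


@pytest.fixture
def dose_table() -> pd.DataFrame:
    return tx.example_dose_mortality()


@pytest.fixture(scope="session")
def restorative_sim():
    """A moderately sized simulated restorative cohort (20/20/20 design)."""
    spec = tx.RestorativeSimSpec(n_genes=3000, seed=7)
    matrix, design, truth = tx.simulate_restorative(spec)
    return matrix.normalize_cpm().filter_low_expression(10), design, truth


@pytest.fixture(scope="session")
def disruptive_sim():
    """A simulated 3-vs-3 disruptive experiment with a designated gene set."""
    spec = tx.DisruptiveSimSpec(
        n_genes=2000, effect_lfc_sd=0.5, geneset_size=66, geneset_boost=3.0, seed=5
    )
    matrix, design, truth = tx.simulate_disruptive(spec)
    return matrix.normalize_cpm().filter_low_expression(10), design, truth


def cpm_matrix(values: np.ndarray, prefix: str = "S") -> tx.ExpressionMatrix:
    """Wrap an array as a CPM-scale matrix without total-count constraints
    (marked filtered, as after gene filtering)."""
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"G{i:04d}" for i in range(len(values))],
        columns=[f"{prefix}{j}" for j in range(np.asarray(values).shape[1])],
    )
    return tx.ExpressionMatrix(df, normalized=True, filtered=True)
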