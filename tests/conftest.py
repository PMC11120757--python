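import numpy as np
import pandas as pd
import pytest

import genefabric as gf


def make_eset(values, condition="N", genes=None):
    """ExpressionSet from a plain 2-D array (genes x replicas)."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=pd.Index(genes, name="gene"),
                      columns=[f"{condition}_{k + 1}" for k in range(arr.shape[1])])
    return gf.ExpressionSet(condition, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture(scope="session")
def block_design():
    """Small two-condition design with a tight correlation block and planted folds."""
    return gf.SyntheticDesign(
        n_genes=300,
        conditions=("N", "T"),
        n_replicas=4,
        cv=0.10,
        seed=20240521,
        regulated={"g50": 3.0, "g51": -3.0},
        cor_blocks=(gf.CorrelationBlock(tuple(f"g{i}" for i in range(1, 7)), rho=0.9999),),
    )


@pytest.fixture(scope="session")
def block_study(block_design):
    esets, truth = gf.generate_expression_set(block_design)
    return esets, truth


@pytest.fixture(scope="session")
def null_study():
    """One condition, independent genes: the null for coordination statistics."""
    design = gf.SyntheticDesign(n_genes=500, conditions=("N",), n_replicas=4, cv=0.10, seed=777)
    esets, truth = gf.generate_expression_set(design)
    return esets["N"], truth
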