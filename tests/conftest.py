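import numpy as np
import pandas as pd
import pytest

from aips import (
    ExpressionMatrix,
    GeneSignature,
    RoiConfig,
    SignatureSpec,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples, handmade values."""
    data = pd.DataFrame(
        [[5.0, 1.0, 3.0, 4.0], [2.0, 2.0, 7.0, 1.0], [10.0, 6.0, 8.0, 9.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def strong_cohort():
    """200 samples, planted 30-gene signature at delta=3 (0.3/0.4/0.3 blocks)."""
    cfg = SimConfig(
        n_samples=200,
        n_genes=300,
        signatures=[SignatureSpec("SIG", k=30, frac_low=0.3, frac_high=0.3,
                                  delta=3.0, frac_down=0.2)],
        seed=11,
    )
    expr, truth = simulate_cohort(cfg)
    return expr, truth


@pytest.fixture(scope="session")
def fast_roi_cfg():
    return RoiConfig(n_trials=2000, seed=7)


@pytest.fixture
def up_sig():
    return GeneSignature("UPSIG", up_genes=frozenset(["gA", "gB", "gC"]))
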