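import numpy as np
import pandas as pd
import pytest

from coldacclim import (
    ExpressionMatrix,
    PlantedTruth,
    StudyDesign,
    call_table,
    generate_study,
)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def bundle():
    """One small synthetic study shared by read-only tests."""
    truth = PlantedTruth(n_genes=800, n_lipids=60, seed=1)
    return generate_study(truth=truth)


@pytest.fixture(scope="session")
def calls(bundle):
    return call_table(bundle.contrasts, bundle.expression)


@pytest.fixture()
def toy_expr(design):
    """Deterministic 6-gene expression matrix over the full 24-sample design."""
    samples = design.sample_table()
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(6, len(samples))),
        index=[f"g{i}" for i in range(6)],
        columns=samples.index,
    )
    return ExpressionMatrix(values=values, samples=samples)
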