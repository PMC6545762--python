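import numpy as np
import pandas as pd
import pytest

import ensemblefs as efs


@pytest.fixture(scope="session")
def default_cohort():
    """Preprocessed default cohort with outcomes, shared across tests."""
    spec = efs.GeneratorSpec(seed=11)
    return efs.derive_outcomes(efs.preprocess(efs.generate_cohort(spec)))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def planted_xy(n=400, p=10, beta=2.5, seed=0):
    """One strongly informative feature among nulls, logistic outcome."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    logits = beta * X[:, 0]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return X, y
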