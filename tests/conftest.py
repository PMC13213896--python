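import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import fedlik as fl


@pytest.fixture(scope="session")
def spec() -> fl.ModelSpec:
    """The case-study model: CKD ~ hypertension + sex + age."""
    return fl.case_study_spec()


@pytest.fixture
def make_dataset(spec):
    """Factory for small synthetic site datasets with the case-study schema."""

    def _make(n=20, seed=0, site_id="toy", beta=(-2.0, 0.8, -0.5, 0.02)):
        rng = np.random.default_rng(seed)
        htn = rng.integers(0, 2, n)
        sex = rng.integers(0, 2, n)
        age = rng.integers(18, 90, n)
        eta = beta[0] + beta[1] * htn + beta[2] * sex + beta[3] * age
        y = (rng.random(n) < expit(eta)).astype(int)
        return fl.SiteDataset(
            site_id,
            pd.DataFrame({"hypertension": htn, "sex": sex, "age": age, "ckd": y}),
        )

    return _make


@pytest.fixture(scope="session")
def binary_spec() -> fl.ModelSpec:
    """Minimal two-parameter model: intercept + one covariate."""
    return fl.ModelSpec(outcome="y", covariates=("x",))


@pytest.fixture
def make_binary_dataset():
    """Factory for two-parameter datasets with a symmetric +-1 covariate,
    which keeps the intercept and slope axes of the likelihood surface
    nearly uncorrelated."""

    def _make(n=400, seed=5, site_id="bin", beta=(-0.4, 0.7)):
        rng = np.random.default_rng(seed)
        x = np.where(np.arange(n) % 2 == 0, -1.0, 1.0)
        eta = beta[0] + beta[1] * x
        y = (rng.random(n) < expit(eta)).astype(int)
        return fl.SiteDataset(site_id, pd.DataFrame({"x": x, "y": y}))

    return _make
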