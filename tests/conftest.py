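import numpy as np
import pandas as pd
import pytest

import replichrom as rc
from replichrom import synthetic as syn


@pytest.fixture(scope="session")
def promoter_dataset():
    """A mid-size promoter dataset at oracle R² ~ 0.5 shared across tests."""
    cfg = syn.SynthConfig(n_regions=1500, seed=3)
    cfg = syn.SynthConfig(**{**cfg.__dict__, "noise_sd": syn.noise_sd_for_r2(cfg, 0.5)})
    return cfg, syn.generate_promoter_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_model(promoter_dataset):
    cfg, ds = promoter_dataset
    design = rc.build_design(ds.features, rc.ExpansionSpec(order=2))
    tr, te = rc.split_train_test(list(ds.features.index), 1000, 7)
    fit = rc.fit_lasso_cv(
        design, ds.timing, k_folds=10, seed=1, n_lambdas=60,
        train_ids=tr, test_ids=te,
    )
    return ds, design, fit, tr, te


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def toy_features(rng, n=200, p=4, prefix="f"):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"{prefix}{i}" for i in range(p)]
    )
    X.index = [f"r{i}" for i in range(n)]
    return X
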