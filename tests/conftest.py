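import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mixlink as ml

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """30-sample planted dataset small enough for per-test reuse."""
    cfg = ml.SynthConfig(
        n_samples=30, n_chemicals=40, n_genes=400, n_factors=3, n_modules=4,
        module_size_range=(30, 50), factor_effect=1.5, noise_sd_chem=0.3,
        missing_rate=0.05, lod_quantile=0.05,
        baseline_log_range=(np.log(20), np.log(2000)), seed=12,
    )
    return cfg, ml.generate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_fit():
    """Two-block SGCCA fit on a correlated Gaussian toy."""
    rng = np.random.default_rng(5)
    z = rng.standard_normal(40)
    X = np.outer(z, rng.standard_normal(6)) + 0.5 * rng.standard_normal((40, 6))
    Y = np.outer(z, rng.standard_normal(9)) + 0.5 * rng.standard_normal((40, 9))
    cfg = ml.SgccaConfig(n_components=2, sparsity_per_block=(0.8, 0.8), seed=5)
    return ml.fit_sgcca([X, Y], cfg)


@pytest.fixture()
def chem_toy():
    """4 samples x 3 chemicals with hand-countable missingness."""
    vals = pd.DataFrame(
        {
            "A": [1.0, 2.0, 3.0, 4.0],
            "B": [np.nan, 2.0, np.nan, 4.0],   # missing 2/4 = 0.50, keep
            "C": [np.nan, np.nan, np.nan, 4.0], # missing 3/4 = 0.75, drop
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return ml.ChemTable(values=vals)
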