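import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chainpk as cp

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """A small generic dataset: 8 samples, standard 9-point grid, noisy curves.

    Zero absorption lag keeps every concentration positive (so MAPE is
    defined); the mixed prescriptions 1#-8# keep every dose positive."""
    return cp.simulate_dataset(
        design=cp.builtin_design().select([f"{i}#" for i in range(1, 9)]),
        compound="ber",
        base=cp.PKParameters(tlag=0.0),
        replicates=1,
        noise=cp.NoiseModel(cv=0.1, seed=7),
    )


def make_chain_dataset(m=12, n=9, latent_scale=0.0, seed=3):
    """Noise-free chain-structured data: y1 = 2*x1 (+ optional latent u),
    y_j = y_{j-1} for j >= 2.  The latent component is invisible from X."""
    r = np.random.default_rng(seed)
    X = np.column_stack([
        r.uniform(0.5, 2.0, m),
        r.uniform(0.1, 1.0, m),
        r.uniform(0.1, 1.0, m),
    ])
    y1 = 2.0 * X[:, 0]
    if latent_scale:
        y1 = y1 + r.uniform(0.0, latent_scale, m)
    Y = np.tile(y1[:, None], (1, n))
    return cp.ConcentrationDataset(
        compound="ber", X=X, Y=Y, grid=cp.standard_time_grid()
    )
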