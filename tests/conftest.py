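import logging

import numpy as np
import pandas as pd
import pytest

from nitrilink.synth import SimConfig, simulate_dataset


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    caplog.set_level(logging.ERROR, logger="nitrilink")


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    cfg = SimConfig(
        seed=7, n_days_period1=20, n_days_period2=20,
        n_nitrifiers=2, n_associates=4, n_noise=10, depth=5000,
        association_strengths=(0.5, 0.6, 0.7, 0.8),
    )
    env, counts, annotation, truth, rate = simulate_dataset(cfg)
    return dict(
        config=cfg, env=env, counts=counts, annotation=annotation,
        truth=truth, rate=rate,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def lognormal_compositional_counts(rng, sigma, n, depth=2000, mu=None):
    """Counts from the log-normal compositional model with basis covariance."""
    d = sigma.shape[0]
    if mu is None:
        mu = np.zeros(d)
    y = rng.multivariate_normal(mu, sigma, size=n)
    w = np.exp(y)
    frac = w / w.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, f) for f in frac])
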