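import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bayesord import MCMCConfig, OrdinalDataset, PriorSpec, simulate


@pytest.fixture(scope="session")
def tiny_data():
    """Fixed (n=30, p=2, K=3) dataset used by the exactness checks."""
    data, truth = simulate(n=30, p=2, K=3, support_size=2, effect=1.0, seed=7)
    return data, truth


@pytest.fixture(scope="session")
def small_config():
    """Short-but-adequate protocol for small-instance fits."""
    return MCMCConfig(
        n_chains=3, n_burnin=500, n_adapt=500, thin=1, n_saved_total=6000, seed=11
    )


def make_dataset(n=40, p=3, K=3, seed=0):
    data, _ = simulate(n=n, p=p, K=K, support_size=min(p, 2), effect=1.0, seed=seed)
    return data


def make_samples(beta, gamma=None, model="II", prior=None, alpha=None, lam=None):
    """Hand-built PosteriorSamples for selection/diagnostics unit tests.

    ``beta``/``gamma`` are (chain, iter, p) arrays (gamma optional).
    """
    from bayesord.samplers import MCMCConfig, PosteriorSamples

    beta = np.asarray(beta, dtype=float)
    n_chains, n_iter, p = beta.shape
    if alpha is None:
        alpha = np.broadcast_to(
            np.array([-1.0, 1.0]), (n_chains, n_iter, 2)
        ).copy()
    if prior is None:
        prior = PriorSpec(model=model, t=0.5)
    cfg = MCMCConfig(
        n_chains=n_chains, n_burnin=0, n_adapt=0, thin=1,
        n_saved_total=n_chains * n_iter, seed=0,
    )
    return PosteriorSamples(
        model=prior.model,
        alpha=np.asarray(alpha, dtype=float),
        beta=beta,
        gamma=None if gamma is None else np.asarray(gamma),
        pi=None,
        lam=lam,
        config=cfg,
        prior=prior,
        feature_ids=tuple(f"feature_{j + 1}" for j in range(p)),
    )
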