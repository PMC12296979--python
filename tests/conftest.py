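import numpy as np
import pytest

from ersppc.gpcm import (
    GpcmParameters,
    ResponseMatrix,
    category_probabilities_matrix,
    thresholds_to_intercepts,
)
from ersppc.posterior import McmcConfig, PosteriorDraws, sample_posterior

# short-chain settings for desk-scale fits; diagnostics thresholds relaxed
# accordingly (full-length defaults keep the strict 1.01/400 bar)
SHORT_MCMC = dict(
    n_burnin=300, n_sampling=700, max_retries=0, rhat_threshold=1.05, ess_threshold=50
)


def simulate_gpcm(
    params: GpcmParameters, theta: np.ndarray, rng: np.random.Generator
) -> ResponseMatrix:
    """Sample a response matrix directly from GPCM category probabilities."""
    probs = category_probabilities_matrix(theta, params)
    u = rng.random(probs.shape[:2])
    resp = (u[:, :, None] > probs.cumsum(axis=-1)).sum(axis=-1) + 1
    return ResponseMatrix(responses=resp, c=params.c)


def random_gpcm_params(
    rng: np.random.Generator, n_items: int, c: int = 4
) -> GpcmParameters:
    slopes = rng.uniform(0.8, 1.8, n_items)
    taus = np.sort(rng.uniform(-1.5, 1.5, (n_items, c - 1)), axis=1)
    intercepts = np.stack(
        [thresholds_to_intercepts(taus[i], slopes[i]) for i in range(n_items)]
    )
    return GpcmParameters(slopes=slopes, intercepts=intercepts)


@pytest.fixture(scope="session")
def recovery_truth():
    """GPCM-simulated dataset with known parameters (N=500, K=24)."""
    rng = np.random.default_rng(20240917)
    params = random_gpcm_params(rng, 24)
    theta = rng.standard_normal((500, 1))
    data = simulate_gpcm(params, theta, rng)
    return params, theta, data


@pytest.fixture(scope="session")
def recovery_fit(recovery_truth):
    params, theta, data = recovery_truth
    cfg = McmcConfig(
        seed=51,
        n_burnin=500,
        n_sampling=1250,
        max_retries=0,
        rhat_threshold=1.05,
        ess_threshold=50,
    )
    draws, report = sample_posterior(data, None, cfg)
    return draws, report


@pytest.fixture(scope="session")
def toy_data():
    """5 x 6 response matrix with two missing cells."""
    resp = np.array(
        [
            [1, 4, 2, 3, 4, 1],
            [2, 3, 3, 2, 2, 3],
            [1, 4, 0, 4, 1, 1],
            [4, 4, 1, 1, 3, 0],
            [2, 2, 2, 3, 3, 2],
        ]
    )
    mask = resp == 0
    return ResponseMatrix(responses=resp, c=4, missing_mask=mask)


@pytest.fixture(scope="session")
def toy_draws(toy_data):
    """Hand-built 20-draw posterior for the toy data (2 pseudo-chains)."""
    rng = np.random.default_rng(99)
    T, n, k, c = 20, toy_data.n_persons, toy_data.n_items, 4
    intercepts = np.zeros((T, k, c))
    intercepts[:, :, 1:] = rng.normal(0, 0.8, (T, k, c - 1))
    return PosteriorDraws(
        theta=rng.normal(0, 1, (T, n, 1)),
        slopes=rng.uniform(0.5, 1.5, (T, k)),
        intercepts=intercepts,
        correlation=np.ones((T, 1, 1)),
        chain_id=np.repeat([0, 1], T // 2),
        dim_of_item=np.zeros(k, dtype=np.int64),
    )
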