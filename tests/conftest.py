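import numpy as np
import pytest

from ntddr import (
    FactorSet,
    GeneratorConfig,
    Hyperparameters,
    PairwiseAssociations,
    SimilaritySet,
    generate,
)


def random_instance(seed: int, dims=(6, 5, 4), rank=3, with_sims=True):
    """Small fully-random problem (tensor, pairwise, similarities, factors)
    used by gradient/objective tests."""
    rng = np.random.default_rng(seed)
    I, J, K = dims
    X = (rng.uniform(size=dims) < 0.3).astype(float)
    P = PairwiseAssociations(
        A_CT=(rng.uniform(size=(I, J)) < 0.4).astype(float),
        A_CD=(rng.uniform(size=(I, K)) < 0.4).astype(float),
        A_TD=(rng.uniform(size=(J, K)) < 0.4).astype(float),
    )
    if with_sims:
        def sym(n):
            M = rng.uniform(size=(n, n))
            return (M + M.T) / 2
        S = SimilaritySet(sym(I), sym(J), sym(K))
    else:
        S = SimilaritySet.zeros(dims)
    F = FactorSet(
        rng.uniform(size=(I, rank)) + 0.1,
        rng.uniform(size=(J, rank)) + 0.1,
        rng.uniform(size=(K, rank)) + 0.1,
    )
    return X, F, P, S


def synthetic_regime(seed: int = 0, **overrides) -> Hyperparameters:
    """The coefficient regime used for fits on synthetic instances: the
    grid-selected couplings at their selected values, the pinned
    coefficients scaled down so the tensor term dominates."""
    base = dict(rank=5, alpha=0.7, lambda_ct=1e-3, lambda_cd=1e-3,
                lambda_td=1e-3, gamma_c=1e-3, gamma_t=1e-4, gamma_d=1e-3,
                seed=seed, tol=1e-8, max_iter=500)
    base.update(overrides)
    return Hyperparameters(**base)


@pytest.fixture(scope="session")
def default_instance():
    return generate(GeneratorConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
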