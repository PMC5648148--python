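import numpy as np
import pytest

from smcdeconv.model import ExpressionMatrix, ParticleState, PriorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_problem(rng):
    """A 3-gene, 2-sample, 2-type instance with moderate priors."""
    I, J, K = 3, 2, 2
    X = rng.uniform(0.5, 2.0, size=(I, K))
    M = rng.dirichlet(np.ones(K), size=J).T
    Y = ExpressionMatrix.from_values(X @ M + 0.1 * rng.standard_normal((I, J)))
    theta = ParticleState(
        X=X + 0.05 * rng.standard_normal((I, K)),
        M=M + 0.05 * rng.standard_normal((K, J)),
        lam=2.0,
    )
    priors = PriorSpec(
        mu_x=np.ones((I, K)),
        nu_x=np.full((I, K), 1.0),
        mu_m=np.full((K, J), 0.5),
        nu_m=np.full((K, J), 2.0),
        alpha=2.0,
        beta=1.0,
    )
    return Y, theta, priors
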