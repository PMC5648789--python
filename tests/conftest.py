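import numpy as np
import pytest

from scpls import ExpressionPair, ScplsParams


def make_random_params(seed, q=5, p=20, kz=1, ku=1, loading_scale=0.6):
    """Random valid parameters for a small model instance."""
    rng = np.random.default_rng(seed)
    return ScplsParams(
        rng.normal(0, loading_scale, (q, kz)),
        rng.normal(0, loading_scale, (p, kz)),
        rng.normal(0, loading_scale, (p, ku)),
        rng.uniform(0.5, 1.5, q),
        rng.uniform(0.5, 1.5, p),
    )


def sample_from_model(params, n, seed, center=True):
    """Draw n cells from the generative model given parameters."""
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n, params.k))
    W = V @ params.B.T + rng.standard_normal((n, params.q + params.p)) \
        * np.sqrt(params.psi)
    pair = ExpressionPair(W[:, : params.q], W[:, params.q:])
    return pair.centered() if center else pair


@pytest.fixture
def small_instance():
    """A small (n=60, q=5, p=20) instance: true params and sampled data."""
    params = make_random_params(11)
    return params, sample_from_model(params, 60, seed=12)
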