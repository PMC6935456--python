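import numpy as np
import pytest

from consonet.model import NetworkParams, OmicsStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(rng, n=12, k=3, m=2, p=2, min_abs_activation=0.0):
    """Random small stack; optionally resample until every pre-activation
    under the companion params is bounded away from the ReLU kink."""
    while True:
        values = rng.uniform(-1.5, 1.5, size=(n, k, m, p))
        labels = np.zeros(n, dtype=int)
        labels[: n // 2] = 1
        rng.shuffle(labels)
        params = make_params(rng, k, m, p)
        a = np.einsum("ikmp,kmp->ikm", values, params.v)
        if min_abs_activation == 0.0 or np.abs(a).min() > min_abs_activation:
            return OmicsStack(values=values, labels=labels), params


def make_params(rng, k=3, m=2, p=2):
    return NetworkParams(
        v=rng.uniform(0.5, 1.5, size=(k, m, p)) * rng.choice([-1, 1], size=(k, m, p)),
        w=rng.uniform(0.5, 1.5, size=(k, m)),
        beta0=float(rng.normal()),
        beta=rng.normal(size=k),
    )


@pytest.fixture
def small_instance(rng):
    """A 12-sample, 3-gene, 2-study, 2-feature stack with companion params."""
    return make_stack(rng)


@pytest.fixture
def kink_free_instance(rng):
    """Instance whose pre-activations stay away from the ReLU kink, so
    numerical differentiation through the network is well posed."""
    return make_stack(rng, min_abs_activation=0.05)
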