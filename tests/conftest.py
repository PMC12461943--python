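import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcgw.synthetic import FixtureSpec, random_reference

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_ref():
    """A gapped o=2, v=2 bundle with four auxiliary functions."""
    return random_reference(FixtureSpec(o=2, v=2, n_aux=4, seed=7))


@pytest.fixture
def tiny_ref():
    """The minimal o=1, v=1 closed-shell bundle."""
    return random_reference(FixtureSpec(o=1, v=1, n_aux=2, seed=3))


@pytest.fixture
def free_ref():
    """A bundle with the interaction switched off (mean-field limit)."""
    return random_reference(
        FixtureSpec(o=2, v=2, n_aux=3, seed=5, coupling_scale=0.0)
    )


def reference_batch(n, max_ov=12, seed0=100, **kw):
    """A deterministic batch of random gapped bundles with o*v <= max_ov."""
    rng = np.random.default_rng(seed0)
    out = []
    for k in range(n):
        while True:
            o = int(rng.integers(1, 4))
            v = int(rng.integers(1, 5))
            if o * v <= max_ov:
                break
        naux = int(rng.integers(2, 6))
        out.append(random_reference(
            FixtureSpec(o=o, v=v, n_aux=naux, seed=seed0 + k, **kw)
        ))
    return out
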