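import numpy as np
import pytest

from ehld_records import EHLDParams, la_rainfall_records


@pytest.fixture(scope="session")
def rainfall():
    """The packaged 10-value LA rainfall lower record chain."""
    return la_rainfall_records()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(
    params=[(1.0, 0.5), (1.0, 2.0), (0.2, 8.0)], ids=lambda p: f"theta{p[0]}-lam{p[1]}"
)
def params(request):
    theta, lam = request.param
    return EHLDParams(theta=theta, lam=lam)
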