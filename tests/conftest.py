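import numpy as np
import pytest

from lacreg.model import RegulatoryParams, paper_grid


@pytest.fixture
def grid():
    return paper_grid()


@pytest.fixture
def example_params():
    """A mid-range parameter set with clear AND-leaning structure."""
    return RegulatoryParams(alpha=20000.0, gamma=150.0, a=0.4, b=120.0,
                            d=15.0, eta=40.0, n=2.0, m=2.0,
                            Km_cAMP=4.0, Km_IPTG=25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_params(rng: np.random.Generator) -> RegulatoryParams:
    """Log-uniform draw over wide admissible ranges (test helper)."""
    lu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return RegulatoryParams(
        alpha=lu(1e2, 1e5), gamma=lu(1e-1, 1e3), a=lu(1e-3, 1e3),
        b=lu(1e-3, 1e3), d=lu(1e-3, 1e3), eta=lu(1.0, 1e3),
        n=lu(0.5, 6.0), m=lu(0.5, 6.0), Km_cAMP=lu(0.05, 100.0),
        Km_IPTG=lu(0.1, 1000.0))
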