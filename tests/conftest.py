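import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import stats

settings.register_profile(
    "minimsim",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("minimsim")


def binom99(n: int, p: float) -> tuple[float, float]:
    """Exact two-sided 99% acceptance interval for a Binomial(n, p) proportion."""
    lo = stats.binom.ppf(0.005, n, p) / n
    hi = stats.binom.ppf(0.995, n, p) / n
    return float(lo), float(hi)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
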