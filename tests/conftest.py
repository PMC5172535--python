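import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def moment_se_of_variance(x: np.ndarray) -> float:
    """Asymptotic standard error of the sample variance of x."""
    v = x.var(ddof=1)
    m4 = np.mean((x - x.mean()) ** 4)
    return float(np.sqrt(max(m4 - v**2, 0.0) / x.size))
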