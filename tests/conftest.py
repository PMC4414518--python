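import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idss import SearchConfig, compute_frequencies, pfg_ceramics
from idss.types import AssemblageCounts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pfg():
    return pfg_ceramics()


@pytest.fixture(scope="session")
def pfg_freqs(pfg):
    return compute_frequencies(pfg)


@pytest.fixture
def raw_config():
    return SearchConfig(comparison_mode="raw", continuity_threshold=0.30, seed=1)


def random_counts(rng, n=None, t=None, total=100):
    """Random instance factory shared by oracle-equivalence tests."""
    n = n if n is not None else int(rng.integers(4, 8))
    t = t if t is not None else int(rng.integers(3, 6))
    freqs = rng.dirichlet(np.ones(t), size=n)
    counts = np.vstack([rng.multinomial(total, row) for row in freqs])
    return AssemblageCounts(
        tuple(f"X{i:02d}" for i in range(n)),
        tuple(f"T{j}" for j in range(t)),
        counts,
    )
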