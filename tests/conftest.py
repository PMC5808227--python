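import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodegap.distance import CODE_OK, DistanceMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_dm(labels, species, matrix, codes=None):
    """DistanceMatrix from an explicit (possibly hand-written) matrix."""
    d = np.asarray(matrix, dtype=float)
    n = np.full(d.shape, 918, dtype=np.int64)
    if codes is None:
        codes = np.zeros(d.shape, dtype=np.uint8)
    return DistanceMatrix(labels, species, d, n, codes)


@pytest.fixture
def dm_builder():
    return build_dm


def random_symmetric_dm(rng, n, n_species=None):
    """Random well-formed distance matrix with species labels, for oracles."""
    n_species = n_species or max(2, n // 3)
    labels = [f"A{i:03d}.1" for i in range(n)]
    species = [f"Genus sp{rng.integers(n_species):02d}" for _ in range(n)]
    raw = rng.uniform(0.0, 0.25, size=(n, n))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0.0)
    return build_dm(labels, species, d)
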