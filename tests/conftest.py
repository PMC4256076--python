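import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_panel():
    """12 strains x 4 variants with one strongly associated gene (G1)."""
    from dyver.dataset_io import ExpressionDataset, GenotypeMatrix

    r = np.random.default_rng(7)
    codes = r.integers(0, 2, size=(12, 4), dtype=np.uint8)
    codes[:, 0] = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]  # causal variant V1
    strains = [f"s{i}" for i in range(12)]
    geno = GenotypeMatrix(strains, ["V1", "V2", "V3", "V4"], codes)
    T = 5
    y1 = r.normal(0.0, 0.5, (12, T))
    y1[codes[:, 0] == 0, 2:] += 2.0  # effect at the last three time points
    y2 = r.normal(0.0, 0.5, (12, T))
    ds = ExpressionDataset(
        ["G1", "G2"], strains, 10.0 * np.arange(T), np.stack([y1, y2])
    )
    return ds, geno
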