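import numpy as np
import pytest

from her2fish import CellObservation, ScoringThresholds


@pytest.fixture(scope="session")
def thresholds():
    return ScoringThresholds()


def make_cells(spec):
    """Build cells from (n, her2, cep17[, cluster]) tuples."""
    cells = []
    for entry in spec:
        n, her2, cep17, *rest = entry
        cluster = bool(rest[0]) if rest else False
        cells.extend(CellObservation(her2, cep17, cluster) for _ in range(n))
    return cells


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
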