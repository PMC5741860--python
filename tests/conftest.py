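import numpy as np
import pytest

from hbdmix import hmm
from hbdmix.data import GenotypeData, MarkerMap


def uniform_map(n_markers: int, spacing: float = 0.01, n_chrom: int = 1) -> MarkerMap:
    """Evenly spaced markers, ``n_markers`` per chromosome."""
    chroms, bps, morgans = [], [], []
    for c in range(1, n_chrom + 1):
        g = np.arange(n_markers) * spacing
        chroms += [str(c)] * n_markers
        morgans += list(g)
        bps += list((np.round(g / 1e-8) + 1).astype(int))
    return MarkerMap(chroms, bps, morgans)


def random_small_model(rng, K: int) -> hmm.HbdModel:
    rates = np.sort(rng.uniform(2.0, 2000.0, size=K))
    mixing = rng.dirichlet(np.ones(K))
    return hmm.HbdModel(rates=rates, mixing=mixing, epsilon=rng.uniform(0.0, 0.05))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def toy_geno():
    """3 individuals x 4 markers with one missing call."""
    codes = np.array(
        [[0, 1, 2, 0],
         [2, 2, 2, 2],
         [1, -1, 0, 1]], dtype=np.int8)
    return GenotypeData(["a", "b", "c"], codes)
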