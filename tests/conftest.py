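import numpy as np
import pytest

from lmcsim.demography import Mothers


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_mothers(
    n_patches: int,
    n: int,
    z: float = 0.3,
    p0: float = 0.2,
    p1: float = 0.8,
    mate_nan: bool = False,
) -> Mothers:
    """Monomorphic, fully occupied engine population (n mothers per patch)."""
    m = n_patches * n
    alleles = np.empty((m, 3, 2))
    alleles[:, 0, :] = z
    alleles[:, 1, :] = p0
    alleles[:, 2, :] = p1
    mate = np.full_like(alleles, np.nan) if mate_nan else alleles.copy()
    return Mothers(
        patch=np.repeat(np.arange(n_patches, dtype=np.int64), n),
        alleles=alleles,
        mate_alleles=mate,
    )
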