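import numpy as np
import pandas as pd
import pytest

from rootgxe.scan import BlockMatrix


def make_block_matrix(indicators: pd.DataFrame, chrom: str = "chr01",
                      donor: str = "japonica") -> BlockMatrix:
    """BlockMatrix over consecutive 100 kb windows from an indicator table."""
    n = indicators.shape[1]
    windows = pd.DataFrame({
        "chrom": chrom,
        "start": [i * 100_000 for i in range(n)],
        "end": [(i + 1) * 100_000 for i in range(n)],
        "donor_group": donor,
    })
    windows.index = [f"{chrom}:{s}-{e}" for s, e in
                     zip(windows["start"], windows["end"])]
    ind = indicators.copy()
    ind.columns = windows.index
    return BlockMatrix(windows=windows, indicators=ind)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)


@pytest.fixture
def small_matrix(rng):
    """Complete 5 genotypes x 4 environments table with main effects + noise."""
    g = np.array([0.0, 1.0, -1.0, 2.0, -2.0])
    e = np.array([10.0, 12.0, 8.0, 11.0])
    Y = 50.0 + g[:, None] + e[None, :] + rng.normal(0, 0.5, (5, 4))
    return pd.DataFrame(Y, index=[f"g{i}" for i in range(5)],
                        columns=[f"e{j}" for j in range(4)])
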