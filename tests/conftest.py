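import numpy as np
import pandas as pd
import pytest

from clipscore.annotation import TranscriptModel, Transcriptome
from clipscore.simulate import SimConfig, simulate_experiment


@pytest.fixture
def toy_txome() -> Transcriptome:
    """Three hand-made transcripts with known UTR/CDS structure."""
    return Transcriptome(
        [
            TranscriptModel("tx1", "geneA", 1000, 100, 700),   # 100 5'UTR, 600 CDS, 300 3'UTR
            TranscriptModel("tx2", "geneB", 2000, 0, 2000),    # all CDS
            TranscriptModel("tx3", "geneC", 500, 200, 400),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated experiment shared across module tests."""
    return simulate_experiment(SimConfig(n_genes=2000, seed=101))


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form normal-equation OLS (independent of scipy's path)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


@pytest.fixture
def ols():
    return ols_oracle
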