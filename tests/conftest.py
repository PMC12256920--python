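import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from prskit.cavi import SumstatsTable
from prskit.ld_store import LDStore, QuantizationSpec, from_dense


def make_sumstats(beta, n=10000.0, meta=None, rsids=None):
    """SumstatsTable from a standardized effect vector (test helper)."""
    beta = np.asarray(beta, dtype=np.float64)
    M = len(beta)
    if meta is not None:
        rsid = meta["rsid"].to_numpy()
        a1 = meta["a1"].to_numpy()
        a2 = meta["a2"].to_numpy()
    else:
        rsid = rsids if rsids is not None else [f"rs{i}" for i in range(M)]
        a1, a2 = ["A"] * M, ["G"] * M
    n = np.broadcast_to(np.asarray(n, dtype=np.float64), (M,))
    return SumstatsTable(pd.DataFrame({
        "rsid": rsid, "a1": a1, "a2": a2, "beta": beta,
        "se": 1.0 / np.sqrt(n), "z": beta * np.sqrt(n), "n": n,
    }))


def random_banded_store(M, bandwidth, seed=0, spec=None, base_rho=0.5):
    """Random PSD-ish banded store: AR(1) correlation truncated to a band."""
    rng = np.random.default_rng(seed)
    rho = base_rho * rng.uniform(0.5, 1.0)
    idx = np.arange(M)
    R = rho ** np.abs(np.subtract.outer(idx, idx))
    mask = np.abs(np.subtract.outer(idx, idx)) <= bandwidth
    return from_dense(R * mask, mask=mask,
                      spec=spec or QuantizationSpec("float64"))


@pytest.fixture
def toy_corr_matrix():
    """A small dense correlation matrix with exact (quantizable) entries."""
    return np.array([
        [1.0, 0.5, 0.25],
        [0.5, 1.0, -0.125],
        [0.25, -0.125, 1.0],
    ])


@pytest.fixture
def toy_store(toy_corr_matrix):
    return from_dense(toy_corr_matrix)
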