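import numpy as np
import pandas as pd
import pytest

from seascapegen.io_core import DepthTable, EnvTable, GenotypeMatrix
from seascapegen.synthetic_data import SimulationParams, simulate_dataset


def make_gm(calls, popmap, tags=None, positions=None):
    """Small GenotypeMatrix from a nested list and sample->location dict."""
    calls = np.asarray(calls, dtype=np.int8)
    samples = list(popmap)
    n_loci = calls.shape[1]
    if tags is None:
        tags = [f"t{j}" for j in range(n_loci)]
    if positions is None:
        positions = list(range(10, 10 + n_loci))
    return GenotypeMatrix(
        samples=samples,
        tags=np.array(tags, dtype=object),
        positions=np.array(positions),
        calls=calls,
        popmap=pd.Series(popmap),
    )


def make_env(n=10, variables=("temperature", "salinity")):
    """Simple monotone environment table over n locations."""
    idx = pd.Index([f"L{i}" for i in range(n)], name="location")
    data = {"latitude": -41 - 0.4 * np.arange(n), "longitude": -72.5 + 0.05 * np.arange(n)}
    for k, v in enumerate(variables):
        mean = 10 + (k + 1) * np.arange(n, dtype=float)
        data[f"{v}_mean"] = mean
        data[f"{v}_min"] = mean - 2
        data[f"{v}_max"] = mean + 2
    return EnvTable(pd.DataFrame(data, index=idx))


@pytest.fixture(scope="session")
def small_dataset():
    """202-individual, ~340-locus dataset with planted adaptive and paralog loci."""
    params = SimulationParams(
        n_neutral_loci=300, n_adaptive_loci=30, n_paralog_loci=10, seed=42
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def neutral_dataset():
    """Neutral-only 10x20 dataset for calibration checks."""
    params = SimulationParams(
        n_neutral_loci=1000,
        n_adaptive_loci=0,
        n_paralog_loci=0,
        n_per_deme=[20] * 10,
        seed=7,
    )
    return simulate_dataset(params)
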