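import numpy as np
import pandas as pd
import pytest

from reefmito.seqio import Alignment, ColonyTable
from reefmito.synthetic_data import SimulationConfig, simulate


def make_meta(colonies, reefs, regions, lat=None, lon=None, heat=None):
    """Build a ColonyTable from parallel lists."""
    n = len(colonies)
    df = pd.DataFrame(
        {
            "colony": colonies,
            "reef": reefs,
            "region": regions,
            "lat": lat if lat is not None else [7.0] * n,
            "lon": lon if lon is not None else [134.0] * n,
            "date": "2019-07-15",
        }
    )
    if heat is not None:
        df["heat_fraction"] = heat
    return ColonyTable(df)


def random_alignment(rng, n, L, missing_rate=0.0):
    """Small random alignment over ACGT with optional N's."""
    X = rng.integers(0, 4, size=(n, L))
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)[X]
    if missing_rate:
        mask = rng.random((n, L)) < missing_rate
        chars = np.where(mask, ord("N"), chars)
    seqs = [chars[i].astype(np.uint8).tobytes().decode() for i in range(n)]
    return Alignment([f"S{i:02d}" for i in range(n)], seqs)


@pytest.fixture(scope="session")
def palau_like():
    """One default-scale synthetic dataset shared by read-only tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture
def small_cfg():
    """A reduced design for fast end-to-end runs."""
    return SimulationConfig(
        n_regions=3,
        reefs_per_region=(3, 3, 2),
        colonies_per_reef=(4, 6),
        L=800,
        n_founders=8,
        n_divergent_founders=2,
        mutation_prob=0.1,
        missing_rate=0.002,
        seed=5,
    )
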