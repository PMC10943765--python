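import numpy as np
import pandas as pd
import pytest

from ftirharvest.simulate import SimConfig, generate_linked_dataset
from ftirharvest.spectra import SpectraSet


def make_spectra(n_rows: int = 4, n_points: int = 20, seed: int = 0,
                 descending: bool = True) -> SpectraSet:
    """Small random SpectraSet on an evenly spaced grid."""
    rng = np.random.default_rng(seed)
    grid = np.arange(n_points, dtype=float) * 4.0 + 450.0
    if descending:
        grid = grid[::-1]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_rows)],
        "month": (np.arange(n_rows) % 12) + 1,
        "part": "stem",
        "replicate": 1,
    })
    return SpectraSet(grid, rng.normal(1.0, 0.3, size=(n_rows, n_points)), meta)


@pytest.fixture(scope="session")
def linked_dataset():
    """One seeded draw of the full synthetic study (spectra + traits + env)."""
    return generate_linked_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: fewer plants/replicates for fast pipeline-level tests."""
    return SimConfig(seed=11, plants_per_month=4, replicates=2)
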