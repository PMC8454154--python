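import numpy as np
import pandas as pd
import pytest

from trophoweb.io import OtuTable, SampleMetadata
from trophoweb.simulate import SimConfig, simulate_foodweb_dataset


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across test modules."""
    cfg = SimConfig(
        n_sites=3,
        n_individuals=5,
        n_soil_per_site=4,
        n_otus_shared=300,
        read_depth=3000,
        seed=7,
    )
    return simulate_foodweb_dataset(cfg)


@pytest.fixture()
def tiny_table():
    counts = np.array(
        [
            [5, 0, 3, 1],
            [0, 2, 0, 4],
            [1, 1, 1, 1],
        ]
    )
    return OtuTable(counts, ["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"])


@pytest.fixture()
def random_table():
    rng = np.random.default_rng(11)
    counts = rng.integers(0, 50, size=(12, 40))
    return OtuTable(counts, [f"s{i}" for i in range(12)], [f"o{j}" for j in range(40)])


def make_metadata(sample_ids, sample_types, sites=None, landuses=None, d15n=None, litter=None):
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "sample_type": sample_types,
            "species": [f"{t}_sp" for t in sample_types],
            "site": sites or ["site1"] * n,
            "landuse": landuses or ["farmland"] * n,
            "delta15N_animal": d15n if d15n is not None else [np.nan] * n,
            "delta15N_litter": litter if litter is not None else [0.0] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(frame)
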