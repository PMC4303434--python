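import numpy as np
import pandas as pd
import pytest

from gie import LandscapeSpec, OccurrenceTable, generate_dataset


def make_table(rows):
    """rows: iterable of (species, lon, lat)."""
    df = pd.DataFrame(rows, columns=["species", "lon", "lat"])
    table, _ = OccurrenceTable.from_dataframe(df)
    return table


@pytest.fixture
def tiny_table():
    return make_table([("sp1", 0.0, 0.0), ("sp1", 0.0, 1.0), ("sp2", 10.0, 10.0)])


@pytest.fixture
def isotropic_table():
    """40 species, each an isotropic 50-record Gaussian cloud (~55 km sd)."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(40):
        clon, clat = rng.uniform(-60, -40), rng.uniform(-20, 0)
        lon = clon + rng.normal(0, 0.5, 50)
        lat = clat + rng.normal(0, 0.5, 50)
        rows += [(f"sp{i:02d}", x, y) for x, y in zip(lon, lat)]
    return make_table(rows)


@pytest.fixture(scope="session")
def planted():
    """A 5-center planted landscape with no widespread species (seed 0)."""
    spec = LandscapeSpec(seed=0, n_widespread=0)
    table, truth = generate_dataset(spec)
    return spec, table, truth
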