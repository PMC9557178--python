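import numpy as np
import pytest

from geoprev import core_io, synthetic


@pytest.fixture
def small_grid_spec():
    return synthetic.GridSpec(
        n_rows=10, n_cols=10, origin_lon=38.0, origin_lat=10.0, cell_size=0.1
    )


@pytest.fixture
def toy_records():
    """Six clusters across two regions and two waves, hand-checkable counts."""
    rows = [
        (1, "2000", 38.0, 9.0, 4, 1, "A"),
        (2, "2000", 38.1, 9.1, 6, 0, "A"),
        (3, "2000", 38.5, 9.0, 10, 5, "B"),
        (4, "2019", 38.0, 9.2, 8, 2, "A"),
        (5, "2019", 38.6, 9.1, 5, 1, "B"),
        (6, "2019", 38.7, 9.3, 7, 0, "B"),
    ]
    return [core_io.ClusterRecord(*r) for r in rows]


@pytest.fixture
def flat_grid():
    return core_io.CovariateGrid(
        name="flat",
        origin_lon=0.0,
        origin_lat=2.0,
        cell_size=0.5,
        values=np.full((5, 6), 7.25),
    )


def make_indexed_grid(n_rows=4, n_cols=5, cell=0.25):
    """Grid whose value at (row, col) is 100*row + col."""
    rows, cols = np.meshgrid(
        np.arange(n_rows), np.arange(n_cols), indexing="ij"
    )
    return core_io.CovariateGrid(
        name="indexed",
        origin_lon=10.0,
        origin_lat=5.0,
        cell_size=cell,
        values=100.0 * rows + cols,
    )
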