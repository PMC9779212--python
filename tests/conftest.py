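import numpy as np
import pytest

from ohsa import (
    ClusterSpec,
    SimulationConfig,
    assign_counts,
    generate_events,
    generate_regions,
    make_fishnet,
)


def grid_points(nrows, ncols, spacing=200.0):
    """Centroids of an nrows x ncols lattice of square cells."""
    return np.array(
        [
            (c * spacing + spacing / 2, r * spacing + spacing / 2)
            for r in range(nrows)
            for c in range(ncols)
        ]
    )


@pytest.fixture(scope="session")
def square_region():
    """One 10 km square study region."""
    return generate_regions(1, 10000.0)


@pytest.fixture(scope="session")
def four_regions():
    return generate_regions(4, 10000.0, seed=7)


@pytest.fixture(scope="session")
def clustered_lattice():
    """A 20x20 lattice with one strong planted cluster plus background."""
    regions = generate_regions(1, 4000.0)
    cfg = SimulationConfig(
        n_events=600,
        background_fraction=400 / 600,
        clusters=[ClusterSpec((2000.0, 2000.0), 200.0, 1.0)],
        seed=11,
    )
    events, truth = generate_events(regions, cfg)
    lat = make_fishnet(regions, 200.0)
    assign_counts(lat, events, "ALL")
    return lat, events, truth
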