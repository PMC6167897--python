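import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tmeprox import (
    AnnotationSet,
    CellTable,
    assign_regions,
    partition_regions,
)
from tmeprox.synthetic import MARKERS


def make_cells(xy, markers=None, radius=0.0, specimen_id="spec", **flag_arrays):
    """Build a CellTable from coordinates and marker flag arrays."""
    xy = np.atleast_2d(np.asarray(xy, float))
    n = len(xy)
    markers = tuple(flag_arrays) if markers is None else tuple(markers)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "radius_um": np.broadcast_to(np.asarray(radius, float), n).copy(),
        }
    )
    for m in markers:
        df[m] = np.asarray(flag_arrays.get(m, np.zeros(n)), np.int8)
    return CellTable(df, markers, specimen_id=specimen_id)


@pytest.fixture
def square_annotations():
    """A 1000x1000 um square tumor with no exclusions."""
    return AnnotationSet(
        tumor_polygons=[Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])]
    )


@pytest.fixture
def square_partition(square_annotations):
    return partition_regions(square_annotations, band_width=100.0)


@pytest.fixture(scope="session")
def sim_specimen():
    """One labeled synthetic specimen with partition and annotations."""
    import numpy as np

    from tmeprox.synthetic import RESPONDER_LIKE, simulate_specimen

    rng = np.random.default_rng(42)
    record, labeled, partition, annotations = simulate_specimen(
        RESPONDER_LIKE, rng, "fixture"
    )
    return record, labeled, partition, annotations


__all__ = ["make_cells"]
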