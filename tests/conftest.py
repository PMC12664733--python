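import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from spatialtme import (Panel, RegionAnnotation, SyntheticConfig,
                        classify_phenotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_square_mm():
    """A 1000×1000 µm (1 mm²) tumor region."""
    return RegionAnnotation(
        tumor_polygons=[Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])],
        case_id="sq")


def make_cells(xy, panel=Panel.CCR8_FOXP3, markers=None, case_id="c1"):
    """Build a classified cell table from coordinates and marker arrays."""
    xy = np.asarray(xy, float).reshape(-1, 2)
    n = len(xy)
    cols = {"case_id": case_id, "panel": panel.value,
            "x_um": xy[:, 0], "y_um": xy[:, 1]}
    names = ("CCR8", "FOXP3") if panel is Panel.CCR8_FOXP3 else ("CD8", "GZMB")
    markers = markers or {}
    for name in names:
        cols[name] = np.asarray(markers.get(name, np.ones(n, bool)), bool)
    return classify_phenotypes(pd.DataFrame(cols))


@pytest.fixture
def small_config():
    """A fast, small-tissue generator configuration for unit tests."""
    return SyntheticConfig(seed=7, n_cases=4, region_um=(1500.0, 1500.0),
                           lambda_treg=120.0, lambda_cd8=240.0)
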