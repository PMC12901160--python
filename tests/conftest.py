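from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sscpheno import CellTable, FOVAnnotation, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_cell_df(panel, cells, fov_id="F1", patient_id="P1", condition="case"):
    """Build a cell-table DataFrame from sparse per-cell specs.

    Each entry of ``cells`` maps column names (meta or target) to values;
    unspecified targets default to 0.
    """
    rows = []
    for i, spec in enumerate(cells):
        row = {
            "cell_id": f"c{i}",
            "patient_id": patient_id,
            "condition": condition,
            "fov_id": fov_id,
            "x_um": 10.0 + i,
            "y_um": 10.0,
            "area_um2": 100.0,
        }
        row.update({name: 0.0 for name in panel.names})
        row.update(spec)
        rows.append(row)
    return pd.DataFrame(rows)


def make_cells(panel, cells, **kw) -> CellTable:
    return CellTable(make_cell_df(panel, cells, **kw), panel)


@pytest.fixture
def simple_fovs():
    return [
        FOVAnnotation("F1", "P1", 0.0, 0.0),
        FOVAnnotation("F2", "P1", 500.0, 0.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
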