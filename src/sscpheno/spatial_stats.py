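"""Spatial statistics: distance to the epithelium, LP cell density, cell size.

Distances are Euclidean centroid-to-centroid, computed per patient in the
global stitched slide frame (µm) across all of the patient's FOVs; a
within-FOV mode is available for exports whose tiles are not co-registered.
Epithelial anchor cells are the EpCAM+ cells of the *unfiltered* table —
they define tissue geometry and are therefore exempt from the follicle
filter (configurable by passing a filtered anchor table).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ValidationError
from .panel_io import CellTable, FOVAnnotation

EPITHELIUM_MARKER = "EpCAM"


def nearest_epithelium_distance(
    cells: CellTable,
    positivity: pd.DataFrame,
    labels: pd.DataFrame,
    anchor_cells: CellTable | None = None,
    anchor_positivity: pd.DataFrame | None = None,
    epithelium_marker: str = EPITHELIUM_MARKER,
    within_fov: bool = False,
) -> pd.DataFrame:
    """Distance from every plasma cell to its nearest EpCAM+ epithelial cell.

    Returns one record per PC: cell_id, patient_id, pc_subtype, distance_um.
    Patients without any EpCAM+ cell get no records (with a warning); a k-d
    tree accelerates the search and is exactly equivalent to an exhaustive
    scan.
    """
    if anchor_cells is None:
        anchor_cells, anchor_positivity = cells, positivity
    if anchor_positivity is None:
        raise ConfigurationError("anchor_cells given without anchor_positivity")
    if epithelium_marker not in anchor_positivity.columns:
        raise ConfigurationError(
            f"epithelium marker {epithelium_marker!r} not in the positivity matrix"
        )

    is_pc = (labels["lineage"] == "PC").to_numpy()
    pc_df = cells.df.loc[is_pc, ["cell_id", "patient_id", "fov_id", "x_um", "y_um"]]
    pc_df = pc_df.assign(pc_subtype=labels.loc[is_pc, "pc_subtype"].to_numpy())

    is_epi = anchor_positivity[epithelium_marker].to_numpy(bool)
    epi_df = anchor_cells.df.loc[is_epi, ["patient_id", "fov_id", "x_um", "y_um"]]

    group_cols = ["patient_id", "fov_id"] if within_fov else ["patient_id"]
    records = []
    for key, pcs in pc_df.groupby(group_cols, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        anchors = epi_df
        for col, val in zip(group_cols, key):
            anchors = anchors[anchors[col] == val]
        if anchors.empty:
            warnings.warn(
                f"no {epithelium_marker}+ anchor cells for {dict(zip(group_cols, key))}; "
                "distances missing",
                stacklevel=2,
            )
            continue
        tree = cKDTree(anchors[["x_um", "y_um"]].to_numpy(float))
        dist, _ = tree.query(pcs[["x_um", "y_um"]].to_numpy(float), k=1)
        for (_, row), d in zip(pcs.iterrows(), np.atleast_1d(dist)):
            records.append(
                {
                    "cell_id": row["cell_id"],
                    "patient_id": row["patient_id"],
                    "pc_subtype": row["pc_subtype"],
                    "distance_um": float(d),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["cell_id", "patient_id", "pc_subtype", "distance_um"]
    )


def median_distance_per_subtype(records: pd.DataFrame) -> pd.DataFrame:
    """Median nearest-epithelium distance per patient × PC subtype (long)."""
    if records.empty:
        return pd.DataFrame(columns=["patient_id", "pc_subtype", "median_distance_um", "n_cells"])
    out = (
        records.groupby(["patient_id", "pc_subtype"], observed=True)["distance_um"]
        .agg(median_distance_um="median", n_cells="size")
        .reset_index()
    )
    return out


def lp_cell_density(
    cells: CellTable,
    fovs: Sequence[FOVAnnotation],
    labels: pd.DataFrame,
) -> pd.Series:
    """Vim+ LP cells per mm² of analysed tissue, per patient.

    The analysed area is approximated by (number of retained, i.e.
    non-follicle, FOVs) × (FOV side / 1000 mm)²; no tissue mask is used.
    Patients with zero retained FOVs get a missing value.
    """
    vim = (labels["lineage"] != "non_LP").to_numpy()
    pids = cells.df["patient_id"].astype(str)
    counts = pids[vim].value_counts()
    area_mm2: dict[str, float] = {}
    for f in fovs:
        if not f.contains_follicle:
            area_mm2[f.patient_id] = area_mm2.get(f.patient_id, 0.0) + (f.side_um / 1000.0) ** 2
    patients = sorted(set(f.patient_id for f in fovs) | set(pids.unique()))
    out = {}
    for pid in patients:
        area = area_mm2.get(pid, 0.0)
        out[pid] = np.nan if area == 0 else counts.get(pid, 0) / area
    s = pd.Series(out, name="vim_cells_per_mm2")
    s.index.name = "patient_id"
    return s


def cell_size_summary(cells: CellTable, labels: pd.DataFrame) -> pd.DataFrame:
    """Median cell area (µm²) per patient × PC subtype."""
    if "area_um2" not in cells.df.columns:
        warnings.warn("cell table has no area_um2 column; cell size stage skipped",
                      stacklevel=2)
        return pd.DataFrame(columns=["patient_id", "pc_subtype", "median_area_um2", "n_cells"])
    is_pc = (labels["lineage"] == "PC").to_numpy()
    df = cells.df.loc[is_pc, ["patient_id", "area_um2"]].assign(
        pc_subtype=labels.loc[is_pc, "pc_subtype"].to_numpy()
    )
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "pc_subtype", "median_area_um2", "n_cells"])
    return (
        df.groupby(["patient_id", "pc_subtype"], observed=True)["area_um2"]
        .agg(median_area_um2="median", n_cells="size")
        .reset_index()
    )


def brute_force_nearest(queries: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """O(n²) exhaustive nearest-neighbour scan; the oracle the k-d tree
    search is verified against."""
    queries = np.asarray(queries, float)
    anchors = np.asarray(anchors, float)
    if anchors.size == 0:
        raise ValidationError("brute_force_nearest: no anchor points")
    d2 = ((queries[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))
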