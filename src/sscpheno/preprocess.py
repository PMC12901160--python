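"""Preprocessing of raw per-cell intensities.

Three rules are applied before any phenotyping:

1. **Isotype background subtraction** — per cell, the intensity of the
   host-matched isotype-control channel is subtracted from each target;
   negative values are set to zero. This removes the cell's nonspecific
   binding/autofluorescence component and feeds all continuous-level
   analyses (per-subtype median levels, embeddings).
2. **Positivity calling** — a cell is positive for a target when its
   intensity reaches the target's cut-off (30 fluorescence units for mouse
   IgG1-hosted antibodies, 100 for rabbit IgG). Calls are made on raw
   intensities by default; the isotype-derived cut-off already accounts for
   background. The basis is configurable.
3. **Follicle FOV exclusion** — all cells in fields of view containing (part
   of) a lymphoid follicle/aggregate are removed, so lamina-propria
   fractions are not distorted by organised B-cell structures.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UsageError
from .panel_io import CellTable, FOVAnnotation, Panel

logger = logging.getLogger(__name__)

PositivityBasis = Literal["raw", "corrected"]


def subtract_isotype_background(cells: CellTable, panel: Panel | None = None) -> CellTable:
    """Per-cell isotype fluorescence subtraction, clamped at zero.

    For each cell ``c`` and non-control target ``t``::

        corrected[c, t] = max(0, raw[c, t] - raw[c, isotype_channel(host(t))])

    The isotype-control columns are dropped from the output; metadata is
    unchanged. Raises :class:`UsageError` if the table is already corrected.
    """
    panel = panel or cells.panel
    if cells.corrected:
        raise UsageError("cell table is already background-subtracted")
    raw = cells.intensities
    gateable = panel.gateable
    bg = {
        host: raw[panel.isotype_channel_for(host)].to_numpy(float)
        for host in {t.host for t in gateable}
    }
    corrected = pd.DataFrame(
        {
            t.name: np.maximum(0.0, raw[t.name].to_numpy(float) - bg[t.host])
            for t in gateable
        },
        index=raw.index,
    )
    return cells.with_intensities(corrected, corrected=True)


def call_positivity(
    cells: CellTable,
    panel: Panel | None = None,
    basis: PositivityBasis = "raw",
) -> pd.DataFrame:
    """Boolean cells × gateable-targets positivity matrix.

    ``positive[c, t]`` iff ``intensity[c, t] >= cutoff(t)`` (boundary
    inclusive). ``basis`` must match the state of the table: ``"raw"``
    requires an uncorrected table, ``"corrected"`` a subtracted one.
    """
    panel = panel or cells.panel
    if basis not in ("raw", "corrected"):
        raise ConfigurationError(f"unknown positivity basis {basis!r}")
    if basis == "raw" and cells.corrected:
        raise UsageError(
            "basis='raw' requires an uncorrected table, got a background-subtracted one"
        )
    if basis == "corrected" and not cells.corrected:
        raise UsageError(
            "basis='corrected' requires a background-subtracted table, got a raw one"
        )
    cutoffs = panel.cutoffs()
    block = cells.intensities[cutoffs.index.tolist()]
    pos = block.to_numpy(float) >= cutoffs.to_numpy(float)[None, :]
    return pd.DataFrame(pos, index=block.index, columns=cutoffs.index.tolist())


def filter_follicle_fovs(
    cells: CellTable, fovs: Sequence[FOVAnnotation]
) -> tuple[CellTable, np.ndarray]:
    """Drop cells whose FOV contains (part of) a lymphoid follicle/aggregate.

    Returns the filtered table and the boolean keep-mask aligned to the
    input rows, so aligned side tables (positivity matrix, corrected
    intensities) can be filtered identically. Idempotent. Logs the number of
    excluded FOVs per patient; warns if nothing is left.
    """
    flagged = {f.fov_id for f in fovs if f.contains_follicle}
    keep = ~cells.df["fov_id"].astype(str).isin(flagged).to_numpy()
    if flagged:
        excluded = (
            cells.df.loc[~keep]
            .groupby("patient_id", observed=True)["fov_id"]
            .nunique()
        )
        for pid, n in excluded.items():
            logger.info("patient %s: excluded %d follicle FOV(s)", pid, n)
    if not keep.any() and len(cells):
        warnings.warn(
            "all FOVs are flagged as follicle-containing; no cells retained "
            "and downstream fractions are undefined",
            stacklevel=2,
        )
    return cells.select_rows(keep), keep
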