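"""Input data model: antibody panel, per-cell expression table, FOV annotations.

The entry point of the analysis is the per-cell expression matrix exported by
the imaging platform after vendor-side segmentation: one row per cell with raw
fluorescence intensities for each of the ~64 protein targets, a centroid in
global slide coordinates (µm), the cell area and the field-of-view (FOV) id.
Two side tables complete the model: the panel definition (target name, host
isotype class, isotype-control flag, optional per-target positivity cut-off)
and the FOV annotation table (origin, edge length, lymphoid-follicle flag).

Everything downstream — background subtraction, gating, spatial statistics —
shares the three validated containers defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MOUSE_IGG1 = "mouse_IgG1"
RABBIT_IGG = "rabbit_IgG"
HOSTS = (MOUSE_IGG1, RABBIT_IGG)

#: Positivity cut-offs (raw fluorescence units) implied by the host isotype
#: class of the detection antibody: 30 for mouse IgG1, 100 for rabbit IgG.
DEFAULT_CUTOFFS: Mapping[str, float] = {MOUSE_IGG1: 30.0, RABBIT_IGG: 100.0}

#: Metadata columns of a cell table, in canonical order. Every other column
#: must be a panel target.
META_COLUMNS = (
    "cell_id",
    "patient_id",
    "condition",
    "fov_id",
    "x_um",
    "y_um",
    "area_um2",
)

#: Centroids may straddle FOV tile borders by up to this much (µm) and still
#: be accepted (with a warning); farther out is an error.
FOV_BOUNDARY_TOLERANCE_UM = 1.0


@dataclass(frozen=True)
class PanelTarget:
    """One antibody target of the multiplexed panel."""

    name: str
    host: str
    is_isotype_control: bool = False
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.host not in HOSTS:
            raise ValidationError(
                f"target {self.name!r}: unknown host isotype class {self.host!r}; "
                f"expected one of {HOSTS}"
            )
        if self.is_isotype_control:
            if self.cutoff is not None:
                raise ValidationError(
                    f"isotype control {self.name!r} must not carry a positivity cutoff"
                )
        else:
            cutoff = self.cutoff if self.cutoff is not None else DEFAULT_CUTOFFS[self.host]
            if cutoff < 0:
                raise ValidationError(f"target {self.name!r}: negative cutoff {cutoff}")
            object.__setattr__(self, "cutoff", float(cutoff))


class Panel:
    """Ordered collection of panel targets with host→isotype-control mapping.

    Exactly one isotype-control channel per host class must be present, so
    every non-control target has a background channel to subtract.
    """

    def __init__(self, targets: Sequence[PanelTarget]):
        self.targets = list(targets)
        names = [t.name for t in self.targets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate target name(s) in panel: {sorted(dupes)}")
        self._controls: dict[str, str] = {}
        for t in self.targets:
            if t.is_isotype_control:
                if t.host in self._controls:
                    raise ValidationError(
                        f"more than one isotype control for host {t.host!r}: "
                        f"{self._controls[t.host]!r} and {t.name!r}"
                    )
                self._controls[t.host] = t.name
        for t in self.targets:
            if not t.is_isotype_control and t.host not in self._controls:
                raise ValidationError(
                    f"target {t.name!r} has host {t.host!r} but the panel has no "
                    f"isotype control for that host"
                )

    # -- views -------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [t.name for t in self.targets]

    @property
    def gateable(self) -> list[PanelTarget]:
        """Targets that receive positivity calls (non-control)."""
        return [t for t in self.targets if not t.is_isotype_control]

    @property
    def gateable_names(self) -> list[str]:
        return [t.name for t in self.gateable]

    @property
    def control_names(self) -> list[str]:
        return [t.name for t in self.targets if t.is_isotype_control]

    def isotype_channel_for(self, host: str) -> str:
        try:
            return self._controls[host]
        except KeyError:
            raise ValidationError(f"no isotype control channel for host {host!r}") from None

    def __getitem__(self, name: str) -> PanelTarget:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(t.name == name for t in self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def cutoffs(self) -> pd.Series:
        """Per-gateable-target positivity cut-off, in panel order."""
        return pd.Series(
            {t.name: t.cutoff for t in self.gateable}, name="cutoff", dtype=float
        ).loc[self.gateable_names]

    def subset(self, names: Iterable[str]) -> "Panel":
        """Panel restricted to ``names`` plus the isotype controls."""
        keep = set(names)
        return Panel([t for t in self.targets if t.name in keep or t.is_isotype_control])

    # -- (de)serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "host": [t.host for t in self.targets],
                "is_isotype_control": [t.is_isotype_control for t in self.targets],
                "cutoff": [t.cutoff for t in self.targets],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Panel":
        required = {"name", "host", "is_isotype_control"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"panel table is missing column(s): {sorted(missing)}")
        targets = []
        for _, row in df.iterrows():
            cutoff = row.get("cutoff")
            if cutoff is not None and (pd.isna(cutoff) or cutoff == ""):
                cutoff = None
            targets.append(
                PanelTarget(
                    name=str(row["name"]),
                    host=str(row["host"]),
                    is_isotype_control=_parse_bool(row["is_isotype_control"]),
                    cutoff=None if cutoff is None else float(cutoff),
                )
            )
        return cls(targets)


@dataclass(frozen=True)
class FOVAnnotation:
    """One imaging tile: a square of side ``side_um`` (default 500 µm =
    0.5 mm) anchored at its lower-left corner in the global slide frame."""

    fov_id: str
    patient_id: str
    origin_x_um: float
    origin_y_um: float
    side_um: float = 500.0
    contains_follicle: bool = False

    def __post_init__(self) -> None:
        if not self.side_um > 0:
            raise ValidationError(f"FOV {self.fov_id!r}: side_um must be > 0")

    def contains(self, x: float, y: float, tol: float = 0.0) -> bool:
        # half-open square so boundary cells belong to exactly one FOV
        return (
            self.origin_x_um - tol <= x < self.origin_x_um + self.side_um + tol
            and self.origin_y_um - tol <= y < self.origin_y_um + self.side_um + tol
        )


class CellTable:
    """Validated per-cell table: metadata columns plus one raw-intensity
    column per panel target, row order preserved from the source file.

    ``corrected`` records whether isotype background subtraction has been
    applied (in which case the control columns are gone and intensities are
    on the background-subtracted scale).
    """

    def __init__(self, df: pd.DataFrame, panel: Panel, corrected: bool = False):
        expected_targets = panel.gateable_names if corrected else panel.names
        missing_meta = [c for c in META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise FormatError(f"cell table is missing metadata column(s): {missing_meta}")
        missing_targets = [c for c in expected_targets if c not in df.columns]
        if missing_targets:
            raise FormatError(f"cell table is missing target column(s): {missing_targets}")
        extra = [c for c in df.columns if c not in META_COLUMNS and c not in expected_targets]
        if extra:
            raise FormatError(
                f"cell table has column(s) not in the panel: {extra}"
            )
        df = df.loc[:, list(META_COLUMNS) + expected_targets].reset_index(drop=True)
        df[list(expected_targets)] = df[list(expected_targets)].astype(float)

        ids = df["cell_id"].astype(str)
        dup = ids[ids.duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate cell_id(s): {sorted(dup.unique())[:5]}")
        coords = df[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(coords).all():
            bad = int(np.where(~np.isfinite(coords).all(axis=1))[0][0])
            raise ValidationError(f"non-finite centroid at row {bad}")
        intens = df[list(expected_targets)].to_numpy(float)
        if not np.isfinite(intens).all():
            r, c = map(int, np.argwhere(~np.isfinite(intens))[0])
            raise ValidationError(
                f"non-finite intensity at row {r}, target {expected_targets[c]!r}"
            )
        if (intens < 0).any():
            r, c = map(int, np.argwhere(intens < 0)[0])
            raise ValidationError(
                f"negative intensity {intens[r, c]} at row {r}, "
                f"target {expected_targets[c]!r}"
            )
        self.df = df
        self.panel = panel
        self.corrected = corrected
        self.target_names = list(expected_targets)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def meta(self) -> pd.DataFrame:
        return self.df[list(META_COLUMNS)]

    @property
    def intensities(self) -> pd.DataFrame:
        return self.df[self.target_names]

    def with_intensities(self, values: pd.DataFrame, corrected: bool) -> "CellTable":
        """New table with the same metadata and replaced intensity block."""
        out = pd.concat([self.meta.reset_index(drop=True), values.reset_index(drop=True)], axis=1)
        return CellTable(out, self.panel, corrected=corrected)

    def select_rows(self, mask: np.ndarray | pd.Series) -> "CellTable":
        sub = self.df.loc[np.asarray(mask)].reset_index(drop=True)
        new = CellTable.__new__(CellTable)
        new.df = sub
        new.panel = self.panel
        new.corrected = self.corrected
        new.target_names = list(self.target_names)
        return new

    def validate_against_fovs(self, fovs: Sequence[FOVAnnotation]) -> None:
        """Cross-reference fov ids and check centroids lie in their square.

        Centroids up to 1 µm outside their declared square are accepted with
        a warning (segmentation centroids can straddle tile borders).
        """
        by_id = {f.fov_id: f for f in fovs}
        unknown = sorted(set(self.df["fov_id"].astype(str)) - set(by_id))
        if unknown:
            raise ValidationError(
                f"cell table references fov_id(s) absent from FOV annotations: {unknown}"
            )
        n_straddling = 0
        for row in self.df.itertuples(index=True):
            f = by_id[str(row.fov_id)]
            if f.contains(row.x_um, row.y_um):
                continue
            if f.contains(row.x_um, row.y_um, tol=FOV_BOUNDARY_TOLERANCE_UM):
                n_straddling += 1
            else:
                raise ValidationError(
                    f"cell {row.cell_id!r} at ({row.x_um:.1f}, {row.y_um:.1f}) lies "
                    f"outside its FOV {f.fov_id!r} square by more than "
                    f"{FOV_BOUNDARY_TOLERANCE_UM} µm"
                )
        if n_straddling:
            warnings.warn(
                f"{n_straddling} cell(s) straddle their FOV boundary by "
                f"<= {FOV_BOUNDARY_TOLERANCE_UM} µm; accepted",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


def read_panel(path: str | Path) -> Panel:
    """Read a panel definition CSV/TSV; cut-offs default from the host class."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"panel file not found: {path}")
    return Panel.from_frame(pd.read_csv(path, sep=_sep_for(path)))


def write_panel(panel: Panel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_cell_table(path: str | Path, panel: Panel, corrected: bool = False) -> CellTable:
    """Read and validate a per-cell expression table (CSV/TSV)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cell table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    return CellTable(df, panel, corrected=corrected)


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    cells.df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_fov_annotations(path: str | Path) -> list[FOVAnnotation]:
    """Read the FOV annotation table; ``side_um`` defaults to 500 µm."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FOV annotation file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        return []
    required = {"fov_id", "patient_id", "origin_x_um", "origin_y_um", "contains_follicle"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"FOV annotation table is missing column(s): {sorted(missing)}")
    seen: set[str] = set()
    out = []
    for _, row in df.iterrows():
        fid = str(row["fov_id"])
        if fid in seen:
            raise ValidationError(f"duplicate fov_id {fid!r} in FOV annotations")
        seen.add(fid)
        side = row.get("side_um", 500.0)
        if side is None or pd.isna(side):
            side = 500.0
        out.append(
            FOVAnnotation(
                fov_id=fid,
                patient_id=str(row["patient_id"]),
                origin_x_um=float(row["origin_x_um"]),
                origin_y_um=float(row["origin_y_um"]),
                side_um=float(side),
                contains_follicle=_parse_bool(row["contains_follicle"]),
            )
        )
    return out


def write_fov_annotations(fovs: Sequence[FOVAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "fov_id": [f.fov_id for f in fovs],
            "patient_id": [f.patient_id for f in fovs],
            "origin_x_um": [f.origin_x_um for f in fovs],
            "origin_y_um": [f.origin_y_um for f in fovs],
            "side_um": [f.side_um for f in fovs],
            "contains_follicle": [f.contains_follicle for f in fovs],
        }
    ).to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_container(directory: str | Path) -> tuple[CellTable, Panel, list[FOVAnnotation]]:
    """Read the single-directory container: cells.csv, panel.csv, fovs.csv."""
    directory = Path(directory)
    panel = read_panel(directory / "panel.csv")
    fovs = read_fov_annotations(directory / "fovs.csv")
    cells = read_cell_table(directory / "cells.csv", panel)
    cells.validate_against_fovs(fovs)
    return cells, panel, fovs
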