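"""Synthetic spatial single-cell proteomics tissue with known ground truth.

The generator emulates the statistical structure the analysis assumes, at the
per-cell expression-matrix level (no pixels, no segmentation): square FOVs
laid in a row along a mucosal strip, an epithelial band (EpCAM+/PanCK+,
Vim-) along the top edge of every FOV, and a lamina-propria compartment
(Vim+) below it populated with T cells, dendritic cells, NK cells, B cells,
plasmablasts and the three plasma-cell maturation subtypes at planted
per-condition fractions. Marker intensities are lognormal with an
isotype-correlated additive background; isotype-control channels carry the
pure background draw, so background subtraction with coupling 1 recovers the
signal component exactly. Optional follicle FOVs receive an extra dense disc
of B cells and are flagged ``contains_follicle``.

Everything is deterministic given the master seed; per-patient seeds are
derived as ``SeedSequence([master_seed, patient_index])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .defaults import MOUSE_CONTROL, RABBIT_CONTROL, default_panel
from .errors import ValidationError
from .panel_io import (
    CellTable,
    FOVAnnotation,
    Panel,
    write_cell_table,
    write_fov_annotations,
    write_panel,
)

PC_SUBTYPE_NAMES = ("CD19+CD45+", "CD19-CD45+", "CD19-CD45-", "other")
IMMUNE_CLASSES = ("T_CD4", "T_CD8", "DC", "NK", "B", "PB", "PC")

#: Markers constitutively positive per cell class (all other targets are
#: drawn from the negative family). PC subtypes add their CD19/CD45 signs.
CLASS_PROFILES: dict[str, frozenset[str]] = {
    "epithelial": frozenset({"EpCAM", "PanCK", "B2M/CD298", "Beta-catenin"}),
    "T_CD4": frozenset({"Vimentin", "CD3", "CD4", "CD45", "B2M/CD298"}),
    "T_CD8": frozenset({"Vimentin", "CD3", "CD8", "CD45", "B2M/CD298"}),
    "DC": frozenset({"Vimentin", "CD11c", "HLA-DR", "CD45", "B2M/CD298"}),
    "NK": frozenset({"Vimentin", "CD56", "GZMB", "CD45", "B2M/CD298"}),
    "B": frozenset({"Vimentin", "CD19", "CD20", "CD27", "CD45", "HLA-DR", "B2M/CD298"}),
    "PB": frozenset({"Vimentin", "CD19", "CD27", "CD38", "CD45", "BCMA", "B2M/CD298"}),
    "PC": frozenset({"Vimentin", "CD138", "CD27", "CD38", "BCMA", "NFkB-p65",
                     "Pan-RAS", "B2M/CD298"}),
}

_SUBTYPE_SIGNS: dict[str, tuple[bool, bool]] = {  # (CD19, CD45)
    "CD19+CD45+": (True, True),
    "CD19-CD45+": (False, True),
    "CD19-CD45-": (False, False),
    "other": (True, False),
}

#: Subtype/class-specific scaling of the positive-family intensity for
#: selected markers, emulating the stepwise loss of activation signalling
#: and the slight CD138 decline along plasma-cell maturation.
DEFAULT_LEVEL_MULTIPLIERS: Mapping[tuple[str, str], float] = {
    ("CD19-CD45+", "NFkB-p65"): 0.55,
    ("CD19-CD45-", "NFkB-p65"): 0.50,
    ("CD19-CD45-", "Pan-RAS"): 0.50,
    ("CD19-CD45+", "CD138"): 0.90,
    ("CD19-CD45-", "CD138"): 0.85,
}

#: Fraction of Ki-67+ (proliferating) cells per class/subtype; early PCs
#: proliferate the most among PCs, terminal PCs barely at all.
DEFAULT_PROLIFERATION_FRACS: Mapping[str, float] = {
    "CD19+CD45+": 0.30,
    "CD19-CD45+": 0.10,
    "CD19-CD45-": 0.05,
    "other": 0.10,
    "B": 0.20,
    "PB": 0.50,
}

#: Median cell area (µm²) per class; PC area creeps up with maturation as
#: secretory organelles expand.
DEFAULT_AREA_MEDIANS: Mapping[str, float] = {
    "epithelial": 110.0,
    "T_CD4": 70.0,
    "T_CD8": 70.0,
    "DC": 90.0,
    "NK": 70.0,
    "B": 75.0,
    "PB": 95.0,
    "CD19+CD45+": 100.0,
    "CD19-CD45+": 110.0,
    "CD19-CD45-": 120.0,
    "other": 105.0,
}


@dataclass(frozen=True)
class LognormalFamily:
    """Draws ``scale * exp(sigma * Z)``; scale 0 means identically zero."""

    scale: float
    sigma: float

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.scale == 0.0:
            return np.zeros(size)
        return self.scale * np.exp(self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class IntensityModel:
    """Lognormal intensity families on the fluorescence scale of the 30/100
    positivity cut-offs: positives well above, negatives and background
    well below."""

    positive: LognormalFamily = LognormalFamily(300.0, 0.4)
    negative: LognormalFamily = LognormalFamily(4.0, 0.4)
    background: LognormalFamily = LognormalFamily(6.0, 0.4)
    coupling: float = 1.0  # additive weight of the per-cell isotype background


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the defaults are the study conditions every
    property test and acceptance check runs under."""

    n_patients_per_condition: int = 6
    n_fovs: int = 8
    fov_side_um: float = 500.0
    cells_per_fov: int = 400
    epithelial_band_frac: float = 0.30
    follicle_fov_frac: float = 0.125
    follicle_cells: int = 150
    immune_composition: Mapping[str, float] = field(
        default_factory=lambda: {
            "T_CD4": 0.31, "T_CD8": 0.18, "DC": 0.12, "NK": 0.08,
            "B": 0.14, "PB": 0.05, "PC": 0.12,
        }
    )
    pc_subtype_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "case": {"CD19+CD45+": 0.446, "CD19-CD45+": 0.25,
                     "CD19-CD45-": 0.155, "other": 0.149},
            "control": {"CD19+CD45+": 0.132, "CD19-CD45+": 0.30,
                        "CD19-CD45-": 0.327, "other": 0.241},
        }
    )
    intensity_model: IntensityModel = IntensityModel()
    proliferation_fracs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROLIFERATION_FRACS)
    )
    level_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_MULTIPLIERS)
    )
    area_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_MEDIANS)
    )
    area_log_sd: float = 0.15
    subtype_distance_bias: Mapping[str, float] = field(
        default_factory=lambda: {"CD19-CD45-": 3.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_per_condition < 1:
            raise ValidationError("n_patients_per_condition must be >= 1")
        if not math.isclose(sum(self.immune_composition.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("immune_composition fractions must sum to 1")
        for cond, fr in self.pc_subtype_fractions.items():
            if set(fr) != set(PC_SUBTYPE_NAMES):
                raise ValidationError(
                    f"pc_subtype_fractions[{cond!r}] must cover exactly {PC_SUBTYPE_NAMES}"
                )
            if not math.isclose(sum(fr.values()), 1.0, abs_tol=1e-9):
                raise ValidationError(
                    f"pc_subtype_fractions[{cond!r}] must sum to 1"
                )
        if not 0 <= self.epithelial_band_frac < 1:
            raise ValidationError("epithelial_band_frac must be in [0, 1)")
        if not 0 <= self.follicle_fov_frac <= 1:
            raise ValidationError("follicle_fov_frac must be in [0, 1]")


def separation_preset(**overrides) -> SyntheticSpec:
    """Noise-free spec: constant positive signal far above every cut-off,
    zero negatives and zero background, so gating must recover the truth
    exactly."""
    base = SyntheticSpec(
        intensity_model=IntensityModel(
            positive=LognormalFamily(1000.0, 0.0),
            negative=LognormalFamily(0.0, 0.0),
            background=LognormalFamily(0.0, 0.0),
            coupling=0.0,
        )
    )
    return replace(base, **overrides)


def patient_seed(master_seed: int, patient_index: int) -> np.random.SeedSequence:
    """Documented per-patient seed derivation rule."""
    return np.random.SeedSequence([int(master_seed), int(patient_index)])


def generate_patient(
    spec: SyntheticSpec,
    patient_id: str,
    condition: str,
    seed: int | np.random.SeedSequence,
    panel: Panel | None = None,
) -> tuple[CellTable, list[FOVAnnotation], pd.DataFrame]:
    """Simulate one patient: cells, FOV annotations and truth labels.

    FOVs are laid left-to-right in a single row; within each FOV the top
    ``epithelial_band_frac`` of the height is the epithelium and the rest is
    lamina propria. Cell classes are multinomial draws from
    ``immune_composition``; PC subtypes from
    ``pc_subtype_fractions[condition]``.
    """
    spec.validate()
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    side = spec.fov_side_um
    lp_height = side * (1.0 - spec.epithelial_band_frac)
    n_follicle = int(round(spec.follicle_fov_frac * spec.n_fovs))

    fovs = [
        FOVAnnotation(
            fov_id=f"{patient_id}_F{i}",
            patient_id=patient_id,
            origin_x_um=i * side,
            origin_y_um=0.0,
            side_um=side,
            contains_follicle=i >= spec.n_fovs - n_follicle,
        )
        for i in range(spec.n_fovs)
    ]

    classes: list[str] = []
    subtypes: list[str] = []
    compartments: list[str] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    fov_ids: list[str] = []

    comp_classes = list(spec.immune_composition)
    comp_p = np.array([spec.immune_composition[c] for c in comp_classes])

    for f in fovs:
        n_epi = int(round(spec.epithelial_band_frac * spec.cells_per_fov))
        n_lp = spec.cells_per_fov - n_epi
        # epithelial band along the top edge
        ex = f.origin_x_um + rng.uniform(0, side, n_epi)
        ey = f.origin_y_um + rng.uniform(lp_height, side, n_epi)
        classes += ["epithelial"] * n_epi
        subtypes += [""] * n_epi
        compartments += ["epithelium"] * n_epi
        xs.append(ex)
        ys.append(ey)
        fov_ids += [f.fov_id] * n_epi
        # lamina propria below
        draw = rng.choice(len(comp_classes), size=n_lp, p=comp_p)
        lp_classes = [comp_classes[i] for i in draw]
        lx = f.origin_x_um + rng.uniform(0, side, n_lp)
        ly = np.empty(n_lp)
        sub = [""] * n_lp
        sub_p = spec.pc_subtype_fractions[condition]
        for i, cls in enumerate(lp_classes):
            if cls == "PC":
                s = rng.choice(PC_SUBTYPE_NAMES, p=[sub_p[k] for k in PC_SUBTYPE_NAMES])
                sub[i] = str(s)
                bias = spec.subtype_distance_bias.get(str(s), 1.0)
                # beta(bias, 1): bias > 1 pulls the cell up toward the band
                ly[i] = f.origin_y_um + lp_height * rng.beta(bias, 1.0)
            else:
                ly[i] = f.origin_y_um + rng.uniform(0, lp_height)
        classes += lp_classes
        subtypes += sub
        compartments += ["LP"] * n_lp
        xs.append(lx)
        ys.append(ly)
        fov_ids += [f.fov_id] * n_lp
        # follicle: an extra dense disc of B cells
        if f.contains_follicle and spec.follicle_cells > 0:
            r = side / 6.0
            cx = f.origin_x_um + side / 2.0
            cy = f.origin_y_um + lp_height / 2.0
            theta = rng.uniform(0, 2 * np.pi, spec.follicle_cells)
            rad = r * np.sqrt(rng.uniform(0, 1, spec.follicle_cells))
            classes += ["B"] * spec.follicle_cells
            subtypes += [""] * spec.follicle_cells
            compartments += ["follicle"] * spec.follicle_cells
            xs.append(cx + rad * np.cos(theta))
            ys.append(cy + rad * np.sin(theta))
            fov_ids += [f.fov_id] * spec.follicle_cells

    n = len(classes)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    cls_arr = np.array(classes, dtype=object)
    sub_arr = np.array(subtypes, dtype=object)

    intensities, areas = _draw_intensities(spec, panel, rng, cls_arr, sub_arr)

    df = pd.DataFrame(
        {
            "cell_id": [f"{patient_id}_c{i:05d}" for i in range(n)],
            "patient_id": patient_id,
            "condition": condition,
            "fov_id": fov_ids,
            "x_um": x,
            "y_um": y,
            "area_um2": areas,
        }
    )
    for name in panel.names:
        df[name] = intensities[name]
    cells = CellTable(df, panel)

    truth = pd.DataFrame(
        {
            "cell_id": df["cell_id"],
            "patient_id": patient_id,
            "condition": condition,
            "true_class": cls_arr,
            "true_pc_subtype": np.where(sub_arr == "", "not_a_PC", sub_arr),
            "compartment": compartments,
        }
    )
    return cells, fovs, truth


def _draw_intensities(
    spec: SyntheticSpec,
    panel: Panel,
    rng: np.random.Generator,
    cls_arr: np.ndarray,
    sub_arr: np.ndarray,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Raw intensity per target: class-profile lognormal signal plus the
    coupled per-cell isotype background; control channels carry the pure
    background draw."""
    n = len(cls_arr)
    model = spec.intensity_model
    hosts = sorted({t.host for t in panel.targets})
    bg = {h: model.background.draw(rng, n) for h in hosts}

    # truth positivity template per cell × target
    gateable = panel.gateable
    truth_pos = np.zeros((n, len(gateable)), dtype=bool)
    col = {t.name: j for j, t in enumerate(gateable)}
    for cls, profile in CLASS_PROFILES.items():
        mask = cls_arr == cls
        if not mask.any():
            continue
        for m in profile:
            if m in col:
                truth_pos[mask, col[m]] = True
    for sub, (cd19, cd45) in _SUBTYPE_SIGNS.items():
        mask = sub_arr == sub
        if not mask.any():
            continue
        truth_pos[mask, col["CD19"]] = cd19
        truth_pos[mask, col["CD45"]] = cd45
    # probabilistic proliferation marker
    if "Ki-67" in col:
        key = np.where(sub_arr != "", sub_arr, cls_arr)
        p = np.array([spec.proliferation_fracs.get(str(k), 0.05) for k in key])
        truth_pos[:, col["Ki-67"]] = rng.uniform(0, 1, n) < p

    # per-cell positive-scale multipliers for selected (class/subtype, marker)
    scale_mult = np.ones((n, len(gateable)))
    key = np.where(sub_arr != "", sub_arr, cls_arr)
    for (k, marker), mult in spec.level_multipliers.items():
        if marker in col:
            scale_mult[key == k, col[marker]] = mult

    pos, neg = model.positive, model.negative
    z = rng.standard_normal((n, len(gateable)))
    signal = np.where(
        truth_pos,
        pos.scale * scale_mult * np.exp(pos.sigma * z),
        (neg.scale * np.exp(neg.sigma * z)) if neg.scale else 0.0,
    )
    out: dict[str, np.ndarray] = {}
    for j, t in enumerate(gateable):
        out[t.name] = signal[:, j] + model.coupling * bg[t.host]
    for t in panel.targets:
        if t.is_isotype_control:
            out[t.name] = bg[t.host]

    area_key = key
    med = np.array([spec.area_medians.get(str(k), 80.0) for k in area_key])
    areas = med * np.exp(spec.area_log_sd * rng.standard_normal(n))
    return out, areas


def generate_cohort(
    spec: SyntheticSpec,
    out_dir: str | Path | None = None,
    conditions: Sequence[str] = ("case", "control"),
    panel: Panel | None = None,
) -> dict[str, tuple[CellTable, list[FOVAnnotation], pd.DataFrame]]:
    """Simulate both conditions; optionally write per-patient containers.

    Patient ids are ``<condition>_<k>``; each patient gets an independent
    stream via :func:`patient_seed`. When ``out_dir`` is given, each patient
    directory receives ``cells.csv``, ``panel.csv``, ``fovs.csv`` and
    ``truth.csv``.
    """
    spec.validate()
    panel = panel or default_panel()
    out: dict[str, tuple[CellTable, list[FOVAnnotation], pd.DataFrame]] = {}
    idx = 0
    for condition in conditions:
        for k in range(spec.n_patients_per_condition):
            pid = f"{condition}_{k + 1}"
            cells, fovs, truth = generate_patient(
                spec, pid, condition, patient_seed(spec.seed, idx), panel=panel
            )
            out[pid] = (cells, fovs, truth)
            idx += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        for pid, (cells, fovs, truth) in out.items():
            d = out_dir / pid
            d.mkdir(parents=True, exist_ok=True)
            write_cell_table(cells, d / "cells.csv")
            write_panel(panel, d / "panel.csv")
            write_fov_annotations(fovs, d / "fovs.csv")
            truth.to_csv(d / "truth.csv", index=False)
    return out


def concat_cohort(
    cohort: Mapping[str, tuple[CellTable, list[FOVAnnotation], pd.DataFrame]],
) -> tuple[CellTable, list[FOVAnnotation], pd.DataFrame]:
    """Stack per-patient outputs into one table/annotation list/truth frame."""
    tables = [c.df for c, _, _ in cohort.values()]
    panel = next(iter(cohort.values()))[0].panel
    fovs = [f for _, fs, _ in cohort.values() for f in fs]
    truth = pd.concat([t for _, _, t in cohort.values()], ignore_index=True)
    cells = CellTable(pd.concat(tables, ignore_index=True), panel)
    return cells, fovs, truth
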