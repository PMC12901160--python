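"""Hierarchical marker gating and the per-patient summary statistics built
on it.

Phenotyping is threshold gating on the boolean positivity matrix, not
clustering. The hierarchy:

* lamina-propria (LP) immune cell — Vimentin+;
* plasma cell (PC) — Vim+ CD138+;
* plasmablast (PB) — Vim+ CD19+ CD27+ CD38+ CD20- CD138- (CD138 negativity
  makes PB and PC mutually exclusive);
* PC maturation subtype — from the CD19/CD45 signs of PCs:
  CD19+CD45+ (early), CD19-CD45+ (intermediate), CD19-CD45- (terminal,
  mature), CD19+CD45- ("other", the remaining combination).

All fractions are expressed per patient relative to the Vim+ LP compartment
(markers) or the CD138+ PC compartment (subtypes), on follicle-filtered
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .defaults import (
    DEFAULT_GATES,
    DEFAULT_PHENOTYPING_EXCLUSIONS,
    NOT_A_PC,
    PC_SUBTYPE_GATES,
    PC_SUBTYPES,
)
from .errors import ConfigurationError, ValidationError
from .panel_io import CellTable, Panel

LINEAGES = ("non_LP", "LP_immune", "PB", "PC")


@dataclass(frozen=True)
class GateExpr:
    """Conjunction of marker-sign requirements, e.g. CD19+ CD27+ CD138-."""

    name: str
    requirements: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, sign in self.requirements.items():
            if sign not in ("+", "-"):
                raise ConfigurationError(
                    f"gate {self.name!r}: marker {marker!r} has sign {sign!r}; "
                    "expected '+' or '-'"
                )
        if not self.requirements:
            warnings.warn(
                f"gate {self.name!r} has no requirements and matches every cell",
                stacklevel=2,
            )

    def evaluate(self, positivity_row: Mapping[str, bool]) -> bool:
        """True iff every required sign matches in this single cell's calls."""
        for marker, sign in self.requirements.items():
            if marker not in positivity_row:
                raise ConfigurationError(
                    f"gate {self.name!r} references unknown target {marker!r}"
                )
            if bool(positivity_row[marker]) != (sign == "+"):
                return False
        return True

    def evaluate_matrix(self, positivity: pd.DataFrame) -> np.ndarray:
        """Vectorised evaluation over a cells × targets boolean matrix."""
        missing = [m for m in self.requirements if m not in positivity.columns]
        if missing:
            raise ConfigurationError(
                f"gate {self.name!r} references unknown target(s) {missing}"
            )
        out = np.ones(len(positivity), dtype=bool)
        for marker, sign in self.requirements.items():
            col = positivity[marker].to_numpy(bool)
            out &= col if sign == "+" else ~col
        return out


def evaluate_gate(positivity_row: Mapping[str, bool], gate: GateExpr) -> bool:
    return gate.evaluate(positivity_row)


def gates_from_config(config: Mapping[str, Mapping[str, str]]) -> dict[str, GateExpr]:
    """Build a named gate library from a plain mapping (e.g. parsed YAML)."""
    return {name: GateExpr(name, dict(reqs)) for name, reqs in config.items()}


def classify_cells(
    positivity: pd.DataFrame,
    gates: Mapping[str, Mapping[str, str] | GateExpr] | None = None,
    subtype_gates: Mapping[str, Mapping[str, str] | GateExpr] | None = None,
) -> pd.DataFrame:
    """Assign each cell a lineage and (for PCs) a maturation subtype.

    Returns a DataFrame aligned to ``positivity`` with columns ``lineage``
    (non_LP / LP_immune / PB / PC) and ``pc_subtype`` (the four subtype
    labels or ``not_a_PC``). Precedence within Vim+ cells: PC, then PB,
    then plain LP_immune.
    """
    gates = _as_gate_exprs(gates or DEFAULT_GATES)
    subtype_gates = _as_gate_exprs(subtype_gates or PC_SUBTYPE_GATES)
    for required in ("LP_immune", "PC", "PB"):
        if required not in gates:
            raise ConfigurationError(f"gate library is missing the {required!r} gate")

    lp = gates["LP_immune"].evaluate_matrix(positivity)
    pc = gates["PC"].evaluate_matrix(positivity)
    pb = gates["PB"].evaluate_matrix(positivity)

    lineage = np.full(len(positivity), "non_LP", dtype=object)
    lineage[lp] = "LP_immune"
    lineage[lp & pb] = "PB"
    lineage[pc] = "PC"  # PC gate implies Vim+; PB gate requires CD138- so disjoint

    subtype = np.full(len(positivity), NOT_A_PC, dtype=object)
    for name, gate in subtype_gates.items():
        subtype[pc & gate.evaluate_matrix(positivity)] = name

    return pd.DataFrame(
        {"lineage": lineage, "pc_subtype": subtype}, index=positivity.index
    )


def _as_gate_exprs(gates) -> dict[str, GateExpr]:
    out = {}
    for name, g in gates.items():
        out[name] = g if isinstance(g, GateExpr) else GateExpr(name, dict(g))
    return out


def _vim_positive(labels: pd.DataFrame) -> np.ndarray:
    return (labels["lineage"] != "non_LP").to_numpy()


# ---------------------------------------------------------------------------
# per-patient summaries
# ---------------------------------------------------------------------------

def marker_fractions(
    labels: pd.DataFrame,
    positivity: pd.DataFrame,
    patient_ids: pd.Series,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-patient percentage of Vim+ LP cells positive for each marker.

    fraction(marker) = 100 * |Vim+ and marker+| / |Vim+|. Patients with no
    Vim+ cell get missing values (never zero).
    """
    markers = list(markers) if markers is not None else list(positivity.columns)
    vim = _vim_positive(labels)
    pids = patient_ids.astype(str).to_numpy()
    rows = {}
    for pid in pd.unique(pids):
        sel = (pids == pid) & vim
        n = int(sel.sum())
        if n == 0:
            warnings.warn(
                f"patient {pid!r} has no Vim+ cells; marker fractions undefined",
                stacklevel=2,
            )
            rows[pid] = pd.Series(np.nan, index=markers)
        else:
            rows[pid] = 100.0 * positivity.loc[sel, markers].sum() / n
    out = pd.DataFrame(rows).T[markers]
    out.index.name = "patient_id"
    return out


def pc_subtype_fractions(
    labels: pd.DataFrame, patient_ids: pd.Series
) -> pd.DataFrame:
    """Per-patient percentage of CD138+ PCs in each maturation subtype.

    The four subtype columns sum to 100 for every patient with at least one
    PC; patients without PCs get missing values.
    """
    is_pc = (labels["lineage"] == "PC").to_numpy()
    pids = patient_ids.astype(str).to_numpy()
    rows = {}
    for pid in pd.unique(pids):
        sel = (pids == pid) & is_pc
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"patient {pid!r} has no PCs; subtype fractions undefined",
                          stacklevel=2)
            rows[pid] = pd.Series(np.nan, index=PC_SUBTYPES)
        else:
            counts = labels.loc[sel, "pc_subtype"].value_counts()
            rows[pid] = pd.Series(
                [100.0 * counts.get(s, 0) / n for s in PC_SUBTYPES], index=PC_SUBTYPES
            )
    out = pd.DataFrame(rows).T[PC_SUBTYPES]
    out.index.name = "patient_id"
    return out


def relative_abundance(
    values: pd.Series, is_control: pd.Series | np.ndarray
) -> pd.Series:
    """Scale per-patient values so the control group's median equals 1."""
    is_control = np.asarray(is_control, dtype=bool)
    if not is_control.any():
        raise ValidationError("relative_abundance: control group is empty")
    ref = float(np.median(values.to_numpy(float)[is_control]))
    if ref == 0:
        raise ValidationError(
            "relative_abundance: control median is 0, scale undefined"
        )
    return values / ref


def subtype_marker_summary(
    corrected: CellTable,
    positivity: pd.DataFrame,
    labels: pd.DataFrame,
    markers: Sequence[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Long-format per patient × PC-subtype × marker summary.

    Columns: ``median_level`` (median background-subtracted intensity per
    cell), ``pct_positive`` (share of positivity calls), ``n_cells``, and —
    when ``reference`` names a subtype — ``rel_median_level`` and
    ``rel_pct_positive``, each divided by the patient's reference-subtype
    value (so the reference row is 1 by construction).
    """
    if not corrected.corrected:
        raise ValidationError("subtype_marker_summary expects a background-subtracted table")
    markers = list(markers) if markers is not None else list(positivity.columns)
    missing = [m for m in markers if m not in corrected.target_names]
    if missing:
        raise ConfigurationError(f"summary markers not in the corrected table: {missing}")
    is_pc = (labels["lineage"] == "PC").to_numpy()
    pids = corrected.df["patient_id"].astype(str).to_numpy()
    records = []
    for pid in pd.unique(pids):
        for subtype in PC_SUBTYPES:
            sel = (pids == pid) & is_pc & (labels["pc_subtype"] == subtype).to_numpy()
            n = int(sel.sum())
            if n == 0:
                continue  # missing, not zeros
            med = corrected.intensities.loc[sel, markers].median()
            pct = 100.0 * positivity.loc[sel, markers].mean()
            for m in markers:
                records.append(
                    {
                        "patient_id": pid,
                        "pc_subtype": subtype,
                        "marker": m,
                        "n_cells": n,
                        "median_level": float(med[m]),
                        "pct_positive": float(pct[m]),
                    }
                )
    out = pd.DataFrame.from_records(
        records,
        columns=["patient_id", "pc_subtype", "marker", "n_cells",
                 "median_level", "pct_positive"],
    )
    if reference is not None:
        if reference not in PC_SUBTYPES:
            raise ConfigurationError(f"unknown reference subtype {reference!r}")
        ref = out[out["pc_subtype"] == reference].set_index(["patient_id", "marker"])
        for pid in out["patient_id"].unique():
            if not (ref.index.get_level_values("patient_id") == pid).any():
                raise ValidationError(
                    f"patient {pid!r} has no {reference!r} cells; "
                    "reference normalisation undefined"
                )
        key = pd.MultiIndex.from_frame(out[["patient_id", "marker"]])
        out["rel_median_level"] = out["median_level"].to_numpy() / ref[
            "median_level"
        ].reindex(key).to_numpy()
        out["rel_pct_positive"] = out["pct_positive"].to_numpy() / ref[
            "pct_positive"
        ].reindex(key).to_numpy()
    return out


def select_phenotyping_targets(
    panel: Panel, exclusions: Iterable[str] | None = None
) -> list[str]:
    """Targets used for PC phenotyping: the panel minus isotype controls
    minus the exclusion list (by default the 13 targets unrelated to the
    B-cell compartment)."""
    exclusions = list(
        exclusions if exclusions is not None else DEFAULT_PHENOTYPING_EXCLUSIONS
    )
    unknown = [e for e in exclusions if e not in panel]
    if unknown:
        raise ConfigurationError(
            f"exclusion target(s) not present in the panel: {unknown}"
        )
    drop = set(exclusions)
    return [n for n in panel.gateable_names if n not in drop]
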