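"""End-to-end orchestration: read/simulate → preprocess → gate → summarise
→ spatial → cohort statistics, with provenance.

Every run resolves its configuration, executes the stages in order, logs one
line per stage with cell/FOV counts in and out, and (when an output
directory is given) writes long-format CSV artefacts plus the resolved
configuration, so each stage's output is independently re-loadable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import adjust_pvalues, mann_whitney, summarize_median_iqr
from .defaults import PC_SUBTYPES
from .errors import ConfigurationError, ValidationError
from .panel_io import CellTable, FOVAnnotation, Panel, read_container
from .phenotype import (
    classify_cells,
    gates_from_config,
    marker_fractions,
    pc_subtype_fractions,
    relative_abundance,
    select_phenotyping_targets,
    subtype_marker_summary,
)
from .preprocess import call_positivity, filter_follicle_fovs, subtract_isotype_background
from .simulate import SyntheticSpec, concat_cohort, generate_cohort
from .spatial_stats import (
    cell_size_summary,
    lp_cell_density,
    median_distance_per_subtype,
    nearest_epithelium_distance,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved run configuration; round-trips through YAML."""

    input_dir: str | None = None          # directory of per-patient containers
    simulate: dict | None = None          # SyntheticSpec overrides, or {} for defaults
    positivity_basis: str = "raw"
    follicle_filter_fractions: bool = True
    follicle_filter_spatial: bool = True
    gates: dict | None = None             # named gate library override
    subtype_gates: dict | None = None
    exclusions: list[str] | None = None   # phenotyping exclusion list override
    condition_map: dict[str, str] = field(default_factory=dict)
    control_label: str = "control"
    reference_subtype: str = "CD19+CD45+"
    within_fov_distances: bool = False
    exact_test_bound: int = 10_000
    adjustment: str = "holm_sidak"
    out_dir: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    config: PipelineConfig
    cells: CellTable
    panel: Panel
    fovs: list[FOVAnnotation]
    positivity: pd.DataFrame
    labels: pd.DataFrame
    patient_summary: pd.DataFrame
    marker_fractions: pd.DataFrame
    subtype_summary: pd.DataFrame
    distances: pd.DataFrame
    distance_medians: pd.DataFrame
    cell_sizes: pd.DataFrame
    comparisons: pd.DataFrame
    truth: pd.DataFrame | None = None


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        spec = SyntheticSpec(**{**config.simulate, "seed": config.seed})
        cohort = generate_cohort(spec)
        cells, fovs, truth = concat_cohort(cohort)
        return cells, cells.panel, fovs, truth
    if config.input_dir is None:
        raise ConfigurationError("config needs either input_dir or simulate")
    root = Path(config.input_dir)
    patient_dirs = sorted(d for d in root.iterdir() if (d / "cells.csv").exists())
    if not patient_dirs:
        raise ValidationError(f"no per-patient containers under {root}")
    tables, panel, fovs = [], None, []
    for d in patient_dirs:
        cells_i, panel_i, fovs_i = read_container(d)
        if panel is None:
            panel = panel_i
        elif panel_i.names != panel.names:
            raise ValidationError(f"panel in {d} differs from the first patient's panel")
        tables.append(cells_i.df)
        fovs.extend(fovs_i)
    cells = CellTable(pd.concat(tables, ignore_index=True), panel)
    return cells, panel, fovs, None


def _map_condition(config: PipelineConfig, conditions: pd.Series) -> pd.Series:
    if not config.condition_map:
        return conditions.astype(str)
    mapped = conditions.astype(str).map(lambda c: config.condition_map.get(c, c))
    return mapped


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    # fail fast on gate/exclusion configuration before any compute
    gates = gates_from_config(config.gates) if config.gates else None
    subtype_gates = (
        gates_from_config(config.subtype_gates) if config.subtype_gates else None
    )

    cells, panel, fovs, truth = _load_inputs(config)
    cells.validate_against_fovs(fovs)
    logger.info("inputs: %d cells, %d FOVs, %d targets", len(cells), len(fovs), len(panel))

    phenotyping_markers = select_phenotyping_targets(panel, config.exclusions)
    if gates:
        for g in list(gates.values()) + list((subtype_gates or {}).values()):
            g.evaluate_matrix(
                pd.DataFrame(np.zeros((0, len(panel.gateable_names)), bool),
                             columns=panel.gateable_names)
            )

    corrected = subtract_isotype_background(cells, panel)
    if config.positivity_basis == "corrected":
        positivity = call_positivity(corrected, panel, basis="corrected")
    else:
        positivity = call_positivity(cells, panel, basis="raw")
    logger.info("positivity called on %s intensities", config.positivity_basis)

    f_cells, keep = filter_follicle_fovs(cells, fovs)
    f_pos = positivity.loc[keep].reset_index(drop=True)
    f_corr = corrected.select_rows(keep)
    logger.info("follicle filter: %d -> %d cells", len(cells), len(f_cells))

    labels = classify_cells(f_pos, gates=gates, subtype_gates=subtype_gates)
    counts = labels["lineage"].value_counts().to_dict()
    logger.info("classification: %s", counts)

    pids = f_cells.df["patient_id"].astype(str)
    cond = _map_condition(config, f_cells.df["condition"]).groupby(pids).first()

    mfrac = marker_fractions(labels, f_pos, pids, markers=phenotyping_markers)
    sfrac = pc_subtype_fractions(labels, pids)

    vim = (labels["lineage"] != "non_LP").to_numpy()
    per_pid = pd.DataFrame({"patient_id": pids})
    vim_n = per_pid[vim].groupby("patient_id").size().reindex(sfrac.index, fill_value=0)
    pb_n = per_pid[(labels["lineage"] == "PB").to_numpy()].groupby("patient_id").size()
    pc_n = per_pid[(labels["lineage"] == "PC").to_numpy()].groupby("patient_id").size()
    pb_frac = 100.0 * pb_n.reindex(sfrac.index, fill_value=0) / vim_n
    pc_frac = 100.0 * pc_n.reindex(sfrac.index, fill_value=0) / vim_n
    is_ctrl = (cond.reindex(sfrac.index) == config.control_label).to_numpy()

    summary = sfrac.copy()
    summary.insert(0, "condition", cond.reindex(sfrac.index))
    summary["pb_pct_of_vim"] = pb_frac
    summary["pc_pct_of_vim"] = pc_frac
    summary["n_vim_cells"] = vim_n
    summary["n_pc_cells"] = pc_n.reindex(sfrac.index, fill_value=0)
    if is_ctrl.any():
        for name, frac in (("pb_rel_abundance", pb_frac), ("pc_rel_abundance", pc_frac)):
            try:
                summary[name] = relative_abundance(frac, is_ctrl)
            except ValidationError as err:  # zero control median: scale undefined
                logger.warning("%s skipped: %s", name, err)

    sub_summary = subtype_marker_summary(
        f_corr, f_pos, labels, markers=phenotyping_markers,
        reference=None,
    )

    # spatial: anchors from the UNfiltered table (geometry is exempt from the
    # follicle filter); queries from the filtered PCs unless configured off
    sp_cells, sp_pos, sp_labels = f_cells, f_pos, labels
    if not config.follicle_filter_spatial:
        sp_cells, sp_pos = cells, positivity
        sp_labels = classify_cells(positivity, gates=gates, subtype_gates=subtype_gates)
    distances = nearest_epithelium_distance(
        sp_cells, sp_pos, sp_labels,
        anchor_cells=cells, anchor_positivity=positivity,
        within_fov=config.within_fov_distances,
    )
    dist_medians = median_distance_per_subtype(distances)
    density = lp_cell_density(f_cells, fovs, labels)
    summary["vim_cells_per_mm2"] = density.reindex(sfrac.index)
    sizes = cell_size_summary(sp_cells, sp_labels)
    logger.info("spatial: %d PC distance records", len(distances))

    comparisons = _compare_groups(summary, config)
    logger.info("statistics: %d comparisons", len(comparisons))

    result = PipelineResult(
        config=config, cells=f_cells, panel=panel, fovs=fovs,
        positivity=f_pos, labels=labels,
        patient_summary=summary.reset_index(),
        marker_fractions=mfrac.reset_index(),
        subtype_summary=sub_summary,
        distances=distances, distance_medians=dist_medians,
        cell_sizes=sizes, comparisons=comparisons, truth=truth,
    )
    if config.out_dir:
        _write_bundle(result)
    return result


def _compare_groups(summary: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Case-vs-control Mann–Whitney comparisons of per-patient statistics."""
    cond = summary["condition"]
    groups = [g for g in cond.dropna().unique()]
    if len(groups) != 2:
        logger.warning("need exactly 2 conditions for comparisons, got %s", groups)
        return pd.DataFrame(
            columns=["metric", "group_case", "group_control", "n_case", "n_control",
                     "median_case", "median_control", "U", "p_value", "method",
                     "adjusted_p"]
        )
    control = config.control_label if config.control_label in groups else groups[1]
    case = next(g for g in groups if g != control)
    metrics = PC_SUBTYPES + ["pb_pct_of_vim", "pc_pct_of_vim", "vim_cells_per_mm2"]
    rows = []
    for metric in metrics:
        if metric not in summary.columns:
            continue
        x = summary.loc[cond == case, metric].dropna()
        y = summary.loc[cond == control, metric].dropna()
        if x.empty or y.empty or (len(x) < 2 and len(y) < 2):
            logger.warning("metric %s: groups too small, test skipped", metric)
            continue
        res = mann_whitney(x, y, exact_bound=config.exact_test_bound)
        med_x, *_ = summarize_median_iqr(x)
        med_y, *_ = summarize_median_iqr(y)
        rows.append(
            {
                "metric": metric, "group_case": case, "group_control": control,
                "n_case": res.n_x, "n_control": res.n_y,
                "median_case": med_x, "median_control": med_y,
                "U": res.statistic, "p_value": res.p_value, "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adjusted_p"] = adjust_pvalues(out["p_value"].to_numpy(), config.adjustment)
    return out


def _write_bundle(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.patient_summary.to_csv(out / "patient_summary.csv", index=False)
    result.marker_fractions.to_csv(out / "marker_fractions.csv", index=False)
    result.subtype_summary.to_csv(out / "subtype_marker_summary.csv", index=False)
    result.distances.to_csv(out / "distances.csv", index=False)
    result.distance_medians.to_csv(out / "distance_medians.csv", index=False)
    result.cell_sizes.to_csv(out / "cell_sizes.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    result.config.to_yaml(out / "resolved_config.yaml")
    with open(out / "run_summary.txt", "w") as fh:
        fh.write(f"sscpheno {__version__}\n")
        fh.write(f"cells analysed: {len(result.cells)}\n")
        fh.write(f"FOVs: {len(result.fovs)}\n")
        fh.write(f"lineage counts: {result.labels['lineage'].value_counts().to_dict()}\n")
        fh.write(f"PC distance records: {len(result.distances)}\n")
        fh.write(f"comparisons: {len(result.comparisons)}\n")
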