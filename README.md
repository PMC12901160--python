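# sscpheno

Phenotyping, spatial and cohort statistics for **spatial single-cell
proteomics (SSCP)** of intestinal tissue — quantifying B-lineage populations
and plasma-cell (PC) maturation subtypes from per-cell multiplexed protein
intensities.

## The problem

Multiplexed tissue imagers export, after vendor-side segmentation, a per-cell
expression matrix: raw fluorescence intensities for ~64 protein targets,
plus each cell's centroid (µm), area and field of view (FOV, 0.5 × 0.5 mm).
From that matrix, mucosal immunology studies need to answer questions such
as: what fraction of lamina-propria (LP) immune cells are B cells or
antibody-secreting cells, how are the three PC maturation stages
distributed, and how close does each stage sit to the epithelium?

`sscpheno` implements that downstream analysis as a tested, reusable
pipeline:

1. **Preprocessing** — per-cell isotype background subtraction
   (`corrected = max(0, raw − isotype_control_of_same_host)`), positivity
   calling against host-class cut-offs (mouse IgG1 → 30, rabbit IgG → 100
   fluorescence units, boundary inclusive), and exclusion of FOVs containing
   lymphoid follicles/aggregates.
2. **Hierarchical gating** — LP immune cells are Vim⁺; PCs are Vim⁺CD138⁺
   with maturation subtypes from CD19/CD45: CD19⁺CD45⁺ (early), CD19⁻CD45⁺
   (intermediate), CD19⁻CD45⁻ (terminal) and CD19⁺CD45⁻ ("other");
   plasmablasts (PBs) are Vim⁺CD19⁺CD27⁺CD38⁺CD20⁻CD138⁻. All fractions are
   normalised per patient to Vim⁺ LP cells (markers) or to CD138⁺ PCs
   (subtypes); relative abundances divide by the control group's median.
3. **Spatial statistics** — per-PC Euclidean distance to the nearest EpCAM⁺
   epithelial cell (k-d tree, exactly equal to the quadratic scan), median
   distance per patient × subtype, Vim⁺ LP cells per mm² of analysed FOV
   area, and median cell area per subtype.
4. **Cohort statistics** — two-tailed Mann–Whitney *U* (exact enumeration
   for small tie-free samples, tie-corrected normal approximation
   otherwise), Holm–Šídák adjustment across comparison families, tie-aware
   Spearman correlation, and median/IQR descriptives.
5. **Synthetic tissue** — a generator that plants all of the above
   (compartment geometry, per-condition subtype mixes, lognormal intensity
   families straddling the cut-offs, follicle FOVs, subtype-specific
   epithelium proximity) with known ground truth, so the entire analysis is
   testable without any external data.

## Worked example

Run the end-to-end pipeline on a simulated 6 + 6 patient cohort (8 FOVs ×
400 cells each) with the default planted case/control subtype mixes:

```python
from sscpheno import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(simulate={}, seed=7))
print(result.patient_summary[["patient_id", "condition",
                              "CD19+CD45+", "CD19-CD45-"]].round(1))
print(result.comparisons.round(4))
```

The per-patient summary (abridged) shows the planted shift — early
CD19⁺CD45⁺ PCs dominate in cases, terminal CD19⁻CD45⁻ PCs in controls:

```
patient_id condition  CD19+CD45+  CD19-CD45-
    case_1      case        42.6        12.5
    case_2      case        48.4        16.0
 control_1   control        12.4        33.3
 control_2   control        15.5        33.9
```

and the comparison table gives the exact Mann–Whitney results per metric:

```
           metric  median_case  median_control     U  p_value  adjusted_p
       CD19+CD45+      43.8975         12.5603  36.0   0.0022      0.0151
       CD19-CD45-      16.0392         34.1138   0.0   0.0050      0.0215
    pb_pct_of_vim       4.4388          5.1531  10.0   0.2290      0.4055
```

With 6 patients per group, complete separation gives the smallest attainable
exact two-sided p of 2/C(12,6) ≈ 0.0022. The distance table confirms the
planted geometry — terminal PCs sit nearest the epithelium:

```
pc_subtype  CD19+CD45+  CD19-CD45+  CD19-CD45-  other
case_1           181.8       149.8       107.8  194.5
```

The same analysis is available from the shell:

```sh
sscpheno simulate --out cohort/ --seed 7
sscpheno run --input cohort/ --out report/ --seed 7
sscpheno report --run-dir report/
```

Real exports are analysed the same way: point `--input` at a directory of
per-patient containers (`cells.csv`, `panel.csv`, `fovs.csv`), or pass a
YAML config (`sscpheno run --config config.yaml`) to override gates,
exclusion lists, the positivity basis, condition labels and stage options.

## Layout

- `sscpheno.panel_io` — panel / cell-table / FOV-annotation data model + CSV IO
- `sscpheno.preprocess` — isotype subtraction, positivity, follicle filter
- `sscpheno.phenotype` — gate library, classification, fraction summaries
- `sscpheno.spatial_stats` — nearest-epithelium distances, density, cell size
- `sscpheno.cohort_stats` — Mann–Whitney, Holm–Šídák, Spearman, median/IQR
- `sscpheno.simulate` — synthetic tissue generator with ground truth
- `sscpheno.pipeline`, `sscpheno.cli` — orchestration and the `sscpheno` CLI

See `docs/methods.md` for the scientific and numerical details.
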