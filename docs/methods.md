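# Methods

## Data model and assumptions

The analysis starts from the per-cell expression matrix a spatial molecular
imager exports after segmentation: one row per cell with raw fluorescence
intensities per antibody target, a centroid in a global slide frame (µm, y
increasing upward), cell area (µm²), FOV id, patient id and condition
label. Three assumptions are inherited from that entry point and not
revisited: segmentation is trusted as given; intensities are non-negative
raw fluorescence (no log transform applied upstream); and FOVs are
0.5 × 0.5 mm squares whose membership is half-open, `[origin, origin+side)`,
so a boundary centroid belongs to exactly one FOV. Centroids up to 1 µm
outside their declared square are accepted with a warning (segmentation
centroids can straddle tile borders); farther out is an error.

A panel is an ordered target list with, per target, a host isotype class
(mouse IgG1 or rabbit IgG) and an isotype-control flag; exactly one control
channel per host class must be present. Positivity cut-offs default from
the host class — 30 fluorescence units for mouse IgG1-hosted targets, 100
for rabbit IgG — and may be overridden per target.

## Preprocessing

**Isotype background subtraction.** Each cell's nonspecific
binding/autofluorescence is estimated by the host-matched isotype-control
channel of that same cell and subtracted from every target of that host,
with negative results set to zero. Control columns are dropped from the
corrected table. Corrected intensities feed continuous-level summaries
(per-subtype median protein levels and, optionally, embeddings); they are
elementwise in `[0, raw]` by construction.

**Positivity.** A cell is positive for a target when its intensity reaches
the cut-off (inclusive boundary: `>= cutoff`; inclusivity is the
deterministic reading of a "cut-off" and is configurable). Calls are made
on **raw** intensities by default — the isotype-derived cut-off already
accounts for typical background — with a `positivity_basis="corrected"`
option for gating on subtracted values instead. Raw-basis calls are by
construction invariant to whether subtraction has been run.

**Follicle exclusion.** FOVs flagged as containing (part of) a lymphoid
follicle/aggregate are removed before any fraction is computed, because
organised B-cell aggregates would distort lamina-propria immune fractions.
The filter is idempotent and, by default, applies to every downstream stage
(fractions, PB/PC gating, spatial statistics); a per-stage override exists
because the case for excluding follicles from PC-subtype summaries is
weaker than for total immune fractions. Epithelial cells serving as
distance anchors are exempt — they define tissue geometry, not an immune
fraction (also configurable).

## Phenotyping

Gating is a pure function of the boolean positivity matrix; no clustering
is involved. The default gate library:

| population | gate |
|---|---|
| LP immune | Vim⁺ |
| plasma cell (PC) | Vim⁺ CD138⁺ |
| plasmablast (PB) | Vim⁺ CD19⁺ CD27⁺ CD38⁺ CD20⁻ CD138⁻ |
| epithelial | EpCAM⁺ |

PC subtypes resolve from the CD19/CD45 signs of cells in the PC gate:
CD19⁺CD45⁺ (early), CD19⁻CD45⁺ (intermediate), CD19⁻CD45⁻ (terminal), and
CD19⁺CD45⁻ as "other" — the one combination the three named maturation
stages leave over. Two design points are deliberate: the PB gate requires
Vim⁺ (LP residency) since every reported immune fraction is within Vim⁺ LP
cells, and PB/PC are mutually exclusive because the PB gate demands CD138⁻.
Gates live in configuration (YAML-ready mappings), so other panels can be
phenotyped without code changes.

Summaries are per patient: marker⁺ percentages of Vim⁺ LP cells; subtype
percentages of CD138⁺ PCs (the four classes sum to 100% whenever a patient
has any PC; patients without PCs yield missing values, never zeros);
PB/PC abundance rescaled so the control group's median equals 1; and per
subtype × marker the median corrected level and percent-positive, optionally
normalised to a reference subtype (default CD19⁺CD45⁺) per patient.
Thirteen targets unrelated to the B-cell compartment (β-catenin, CD16, CD3,
CD4, CD56, CD68, CD8, EGFR, EpCAM, fibronectin, FOXP3, Her2, SMA) are
excluded from PC phenotyping summaries by default; the exclusion list is
validated against the panel so spelling drift fails loudly.

## Spatial statistics

Per-PC distance to the epithelium is the Euclidean centroid distance to the
nearest EpCAM⁺ cell of the same patient, computed with a k-d tree that is
exactly equivalent to the exhaustive scan (verified in tests). Distances
default to the stitched global frame across all of a patient's FOVs —
tissue is contiguous and nothing restricts proximity to a tile — with a
within-FOV mode for exports whose tiles are not co-registered. Equidistant
anchors are broken arbitrarily; only the distance is consumed downstream.
LP cell density is Vim⁺ cells per mm², with analysed area approximated by
(number of retained FOVs) × (side/1000)²; no tissue mask is attempted
because the export carries none — densities are therefore comparable within
a study but underestimate true LP density wherever a FOV is partly empty.

## Cohort statistics

Group comparisons use the two-tailed Mann–Whitney *U* test with
`U = #{x_i > y_j} + ½·ties`. The exact null distribution is used whenever
`n_x · n_y ≤ 10,000` and the pooled sample is tie-free; otherwise the
normal approximation with tie-corrected variance and continuity correction.
Families of comparisons are reported both unadjusted and with the
Holm–Šídák step-down (`adj_(i) = max_{j≤i} 1 − (1 − p_(j))^(m−j+1)`),
since per-comparison reporting and familywise control are both defensible
for marker panels. Spearman's ρ is the Pearson correlation of mid-ranks,
with an exact permutation p for tie-free n ≤ 9 and the t-approximation
otherwise; constant inputs yield a missing ρ. Quartiles use linear
interpolation between order statistics (type 7) — note that some GUI
statistics packages use a different quartile convention, so IQRs may differ
slightly from theirs; the convention is configurable at the numpy level and
never load-bearing. Automated outlier removal (e.g. ROUT) is intentionally
not implemented; reports flag this as a divergence from GUI-based
workflows. Two-way ANOVA/post-hoc machinery is out of scope — standard
statsmodels routines can be applied to the exported per-patient tables.

## Synthetic tissue generator

The generator emulates the statistical structure the pipeline assumes, at
the expression-matrix level. Geometry: FOVs laid left-to-right in a single
row (a mucosal strip), the top 30% of each FOV's height filled with
epithelial cells (EpCAM/PanCK/B2M-CD298 positive, Vim negative) and the
rest with LP cells placed uniformly. Cell classes are multinomial draws
from the LP composition (defaults: T CD4 0.31, T CD8 0.18, DC 0.12, NK
0.08, B 0.14, PB 0.05, PC 0.12 — chosen so PCs are ~12% of Vim⁺ cells,
matching the magnitude typical of colonic LP exports); PC subtypes are
drawn per condition, defaulting to case 0.446/0.25/0.155/0.149 and control
0.132/0.30/0.327/0.241 for early/intermediate/terminal/other — mixes that
echo the group medians reported for Crohn's-remission versus non-IBD
colonic tissue, so the planted effect size is the one the analysis is meant
to detect.

Intensities are lognormal — multiplicative noise is the norm for
immunofluorescence — with three families on the fluorescence scale of the
30/100 cut-offs: positive `300·e^{0.4Z}`, negative `4·e^{0.4Z}`, and
isotype background `6·e^{0.4Z}` added to every target of the matching host
(coupling 1.0); the isotype-control channels carry the pure background
draw, so subtraction recovers the signal component exactly. These defaults
straddle the cut-offs realistically while keeping per-marker flip
probabilities near 10⁻³, i.e. gating noise well below multinomial sampling
noise. A noise-free "separation preset" (constant positives at 1000, zero
negatives and background) exists for exact-recovery tests. Selected markers
carry subtype-specific level multipliers (NF-κB p65 and pan-RAS stepping
down along maturation, CD138 declining slightly) and Ki-67 positivity is
probabilistic per class (30%/10%/5% across the three maturation stages).
Terminal CD19⁻CD45⁻ PCs are pulled toward the epithelial band by drawing
their height as `lp_height · Beta(3, 1)`, planting the proximity ordering.
Follicle FOVs (12.5% of FOVs by default, i.e. 1 of 8) receive an extra
disc of 150 B cells — a flag plus plausible contents, not germinal-centre
biology. Cell areas are lognormal per class with medians rising from 100 to
120 µm² along PC maturation.

Per-patient streams derive from the master seed as
`SeedSequence([master_seed, patient_index])`, so any patient can be
regenerated alone, bit-identically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation errors and doublets, spatial
autocorrelation of intensities, spillover between neighbouring cells,
batch/run effects between experiments, between-patient variation in
cellularity and background level (every patient shares one intensity model,
which is why simulated LP densities are nearly constant across patients),
and continuous marker gradients (class profiles are binary positive/
negative apart from the listed multipliers). Recovery results certify the
pipeline's correctness on data that satisfies its assumptions, not
robustness to upstream artefacts.

## Problem sizes and numerical choices

Default study conditions are 6 + 6 patients, 8 FOVs × 400 cells per
patient. The test suite and acceptance script scale some checks: noise-free
recovery uses 10 patients × 8 FOVs × 400 cells; planted-fraction recovery
uses a PC-enriched composition (60% PCs, 600 cells/FOV) so one patient
carries ~2,000 PCs, averaged over 20 seeds; detection power uses 50 cohorts
of 6 + 6 patients at 4 FOVs × 300 cells — ~100 PCs per patient, enough that
the planted case/control mixes separate the groups almost completely while
keeping the whole run in tens of seconds. With 6 vs 6 patients the smallest
attainable exact two-sided Mann–Whitney p is 2/924 ≈ 0.0022.

Other numerical choices: positivity boundaries are inclusive; subtraction
clamps at zero; empty groups propagate as missing values, never zeros;
fractions are undefined (missing, with a warning) for patients with no
denominator cells; the exact-test bound (`n_x·n_y ≤ 10,000`) trades
enumeration cost against approximation accuracy and matches the cohort
sizes this package targets; p-values are clipped to 1; all randomness flows
from explicit seeds and the pipeline is bit-reproducible given
configuration + seed.

## Known limitations

- Tissue area uses FOV counts, not a mask (documented approximation).
- The exact Mann–Whitney path requires tie-free data; tied per-patient
  fractions (possible at small cell counts) fall back to the tie-corrected
  approximation.
- The "multiple Mann–Whitney" adjustment convention is reported both ways
  (unadjusted and Holm–Šídák) rather than asserting one.
- UMAP/embedding rendering is not part of the pipeline contract; corrected
  intensities restricted to the phenotyping targets can be exported to any
  embedding tool.
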