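"""Synthetic tissue generator: determinism, geometry, planted structure."""

import numpy as np
import pandas as pd
import pytest

from sscpheno import (
    SyntheticSpec,
    call_positivity,
    classify_cells,
    concat_cohort,
    generate_cohort,
    generate_patient,
    separation_preset,
    subtract_isotype_background,
)
from sscpheno.errors import ValidationError
from sscpheno.simulate import patient_seed

SMALL = dict(n_patients_per_condition=1, n_fovs=4, cells_per_fov=150)


class TestDeterminism:
    def test_same_seed_same_tables(self):
        spec = SyntheticSpec(**SMALL)
        a, fovs_a, truth_a = generate_patient(spec, "P1", "case", seed=7)
        b, fovs_b, truth_b = generate_patient(spec, "P1", "case", seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)
        pd.testing.assert_frame_equal(truth_a, truth_b)
        assert fovs_a == fovs_b

    def test_different_seeds_differ(self):
        spec = SyntheticSpec(**SMALL)
        a, *_ = generate_patient(spec, "P1", "case", seed=7)
        b, *_ = generate_patient(spec, "P1", "case", seed=8)
        assert not a.df.equals(b.df)

    def test_cohort_reproducible_piecewise(self):
        """A patient regenerated alone from the documented per-patient seed
        rule matches the one inside the full cohort."""
        spec = SyntheticSpec(**SMALL, seed=3)
        cohort = generate_cohort(spec)
        pid = "case_1"
        alone, *_ = generate_patient(spec, pid, "case", patient_seed(3, 0))
        pd.testing.assert_frame_equal(cohort[pid][0].df, alone.df)


class TestValidation:
    def test_fractions_must_sum_to_one(self):
        comp = dict(SyntheticSpec().immune_composition)
        comp["PC"] += 0.05
        with pytest.raises(ValidationError, match="sum to 1"):
            SyntheticSpec(immune_composition=comp).validate()

    def test_subtype_fractions_must_cover_all_four(self):
        with pytest.raises(ValidationError, match="cover exactly"):
            SyntheticSpec(
                pc_subtype_fractions={"case": {"CD19+CD45+": 1.0},
                                      "control": {"CD19+CD45+": 1.0}}
            ).validate()


class TestGeometry:
    def test_follicle_fov_count(self):
        spec = SyntheticSpec(n_fovs=8, follicle_fov_frac=0.25, **{
            k: v for k, v in SMALL.items() if k != "n_fovs"})
        _, fovs, _ = generate_patient(spec, "P1", "case", seed=0)
        assert sum(f.contains_follicle for f in fovs) == 2

    def test_cells_lie_inside_their_fov(self):
        spec = SyntheticSpec(**SMALL)
        cells, fovs, _ = generate_patient(spec, "P1", "case", seed=1)
        cells.validate_against_fovs(fovs)  # raises on violation

    def test_epithelium_in_top_band_lp_below(self):
        spec = SyntheticSpec(**SMALL)
        cells, fovs, truth = generate_patient(spec, "P1", "case", seed=2)
        band_y = spec.fov_side_um * (1 - spec.epithelial_band_frac)
        epi = truth["compartment"] == "epithelium"
        assert (cells.df.loc[epi.to_numpy(), "y_um"] >= band_y).all()
        lp = truth["compartment"] == "LP"
        assert (cells.df.loc[lp.to_numpy(), "y_um"] < band_y).all()

    def test_intensities_nonnegative(self):
        spec = SyntheticSpec(**SMALL)
        cells, *_ = generate_patient(spec, "P1", "case", seed=3)
        assert (cells.intensities.to_numpy() >= 0).all()


class TestPlantedStructure:
    def test_background_cancels_exactly_with_unit_coupling(self):
        """With coupling 1 the isotype channel carries the exact per-cell
        background, so subtraction returns the pure signal component."""
        spec = SyntheticSpec(**SMALL)
        cells, _, truth = generate_patient(spec, "P1", "case", seed=4)
        corrected = subtract_isotype_background(cells)
        # negatives of a pure-signal-zero class: epithelium has no Vimentin
        # signal, so corrected Vimentin is exactly the negative family draw,
        # strictly below the raw value which includes background
        epi = (truth["true_class"] == "epithelial").to_numpy()
        raw_v = cells.intensities.loc[epi, "Vimentin"]
        cor_v = corrected.intensities.loc[epi, "Vimentin"]
        assert (cor_v <= raw_v).all()
        ctrl = cells.intensities.loc[epi, "Ms-IgG1-ctrl"]
        np.testing.assert_allclose(cor_v, np.maximum(0, raw_v - ctrl))

    def test_noise_free_recovery_is_exact(self):
        spec = separation_preset(**SMALL)
        cells, fovs, truth = generate_patient(spec, "P1", "case", seed=5)
        labels = classify_cells(call_positivity(cells))
        non_follicle = ~truth["compartment"].eq("follicle").to_numpy()
        expect_pc = truth["true_class"].eq("PC").to_numpy()
        assert (labels["lineage"].to_numpy()[expect_pc] == "PC").all()
        got = labels["pc_subtype"].to_numpy()[expect_pc]
        assert (got == truth["true_pc_subtype"].to_numpy()[expect_pc]).all()
        epi = truth["true_class"].eq("epithelial").to_numpy()
        assert (labels["lineage"].to_numpy()[epi] == "non_LP").all()
        assert non_follicle.any()

    def test_empirical_class_fractions_converge(self):
        """Large lamina propria: empirical class mix within 1.5 pp of spec."""
        spec = SyntheticSpec(n_patients_per_condition=1, n_fovs=8,
                             cells_per_fov=1800, follicle_fov_frac=0.0)
        _, _, truth = generate_patient(spec, "P1", "control", seed=6)
        lp = truth[truth["compartment"] == "LP"]
        frac = lp["true_class"].value_counts(normalize=True)
        for cls, expected in spec.immune_composition.items():
            assert frac.get(cls, 0.0) == pytest.approx(expected, abs=0.015)

    def test_condition_specific_subtype_fractions(self):
        spec = SyntheticSpec(n_patients_per_condition=1, n_fovs=8,
                             cells_per_fov=1200)
        _, _, t_case = generate_patient(spec, "P1", "case", seed=7)
        pcs = t_case[t_case["true_pc_subtype"] != "not_a_PC"]
        frac = pcs["true_pc_subtype"].value_counts(normalize=True)
        planted = spec.pc_subtype_fractions["case"]
        for sub, expected in planted.items():
            assert frac.get(sub, 0.0) == pytest.approx(expected, abs=0.06)

    def test_distance_bias_orders_subtypes(self):
        """CD19-CD45- PCs are planted nearer the epithelial band."""
        spec = SyntheticSpec(n_patients_per_condition=1, n_fovs=8,
                             cells_per_fov=800)
        cells, fovs, truth = generate_patient(spec, "P1", "control", seed=8)
        band_y = spec.fov_side_um * (1 - spec.epithelial_band_frac)
        pcs = truth["true_pc_subtype"]
        y = cells.df["y_um"]
        d_term = band_y - y[(pcs == "CD19-CD45-").to_numpy()]
        d_early = band_y - y[(pcs == "CD19+CD45+").to_numpy()]
        assert d_term.median() < d_early.median()


class TestCohortIO:
    def test_container_layout_and_truth(self, tmp_path):
        spec = SyntheticSpec(**SMALL, seed=1)
        cohort = generate_cohort(spec, out_dir=tmp_path)
        assert set(cohort) == {"case_1", "control_1"}
        for pid in cohort:
            d = tmp_path / pid
            for name in ("cells.csv", "panel.csv", "fovs.csv", "truth.csv"):
                assert (d / name).exists()

    def test_concat_cohort_shapes(self):
        spec = SyntheticSpec(**SMALL, seed=1)
        cells, fovs, truth = concat_cohort(generate_cohort(spec))
        assert len(cells) == len(truth)
        assert len(fovs) == 2 * spec.n_fovs
        assert set(truth["condition"]) == {"case", "control"}
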