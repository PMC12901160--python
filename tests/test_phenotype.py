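"""Gating hierarchy, fraction/abundance summaries and their oracles."""

import numpy as np
import pandas as pd
import pytest

from sscpheno import (
    GateExpr,
    classify_cells,
    default_panel,
    evaluate_gate,
    marker_fractions,
    pc_subtype_fractions,
    relative_abundance,
    select_phenotyping_targets,
    subtract_isotype_background,
    subtype_marker_summary,
)
from sscpheno.defaults import DEFAULT_GATES, PC_SUBTYPE_GATES, PC_SUBTYPES
from sscpheno.errors import ConfigurationError, ValidationError

from conftest import make_cells

PB_GATE = GateExpr("PB", {"CD19": "+", "CD27": "+", "CD38": "+", "CD20": "-", "CD138": "-"})


def brute_force_classify(row: dict) -> tuple[str, str]:
    """Independent per-cell re-derivation of the hierarchy, straight from
    the gate definitions: Vim+ -> LP; Vim+CD138+ -> PC with CD19/CD45
    subtype; Vim+CD19+CD27+CD38+CD20-CD138- -> PB."""
    if not row["Vimentin"]:
        return "non_LP", "not_a_PC"
    if row["CD138"]:
        key = (row["CD19"], row["CD45"])
        subtype = {
            (True, True): "CD19+CD45+",
            (False, True): "CD19-CD45+",
            (False, False): "CD19-CD45-",
            (True, False): "other",
        }[key]
        return "PC", subtype
    if row["CD19"] and row["CD27"] and row["CD38"] and not row["CD20"]:
        return "PB", "not_a_PC"
    return "LP_immune", "not_a_PC"


class TestGateExpr:
    def test_pb_gate_matches_pb_profile(self):
        row = {"CD19": True, "CD27": True, "CD38": True, "CD20": False, "CD138": False}
        assert evaluate_gate(row, PB_GATE) is True

    def test_cd138_positive_fails_pb_gate(self):
        row = {"CD19": True, "CD27": True, "CD38": True, "CD20": False, "CD138": True}
        assert evaluate_gate(row, PB_GATE) is False

    def test_empty_gate_is_vacuously_true_with_warning(self):
        with pytest.warns(UserWarning, match="matches every cell"):
            gate = GateExpr("empty", {})
        assert gate.evaluate({"CD19": False}) is True

    def test_unknown_target_is_configuration_error(self):
        gate = GateExpr("bad", {"CD3x": "+"})
        with pytest.raises(ConfigurationError, match="CD3x"):
            gate.evaluate({"CD19": True})

    def test_invalid_sign_rejected(self):
        with pytest.raises(ConfigurationError, match="sign"):
            GateExpr("bad", {"CD19": "±"})


class TestClassifyCells:
    def _positivity(self, rows):
        panel = default_panel()
        df = pd.DataFrame(
            [{n: False for n in panel.gateable_names} | r for r in rows]
        )
        return df[panel.gateable_names]

    def test_early_pc(self):
        pos = self._positivity(
            [{"Vimentin": True, "CD138": True, "CD19": True, "CD45": True}]
        )
        labels = classify_cells(pos)
        assert labels.loc[0, "lineage"] == "PC"
        assert labels.loc[0, "pc_subtype"] == "CD19+CD45+"

    def test_terminal_pc(self):
        pos = self._positivity([{"Vimentin": True, "CD138": True}])
        labels = classify_cells(pos)
        assert labels.loc[0, "pc_subtype"] == "CD19-CD45-"

    def test_other_subtype_is_cd19pos_cd45neg(self):
        pos = self._positivity([{"Vimentin": True, "CD138": True, "CD19": True}])
        assert classify_cells(pos).loc[0, "pc_subtype"] == "other"

    def test_vim_negative_is_non_lp_regardless_of_markers(self):
        pos = self._positivity([{"CD138": True, "CD19": True, "CD45": True}])
        labels = classify_cells(pos)
        assert labels.loc[0, "lineage"] == "non_LP"
        assert labels.loc[0, "pc_subtype"] == "not_a_PC"

    def test_pb_requires_cd138_negative(self):
        pos = self._positivity(
            [{"Vimentin": True, "CD19": True, "CD27": True, "CD38": True}]
        )
        assert classify_cells(pos).loc[0, "lineage"] == "PB"

    def test_oracle_equivalence_on_random_matrices(self, rng):
        """Vectorised classification agrees with per-cell brute force."""
        panel = default_panel()
        for _ in range(10):
            n = int(rng.integers(1, 200))
            pos = pd.DataFrame(
                rng.uniform(size=(n, 62)) < 0.35, columns=panel.gateable_names
            )
            labels = classify_cells(pos)
            for i in range(n):
                lin, sub = brute_force_classify(pos.iloc[i].to_dict())
                assert labels.loc[i, "lineage"] == lin
                assert labels.loc[i, "pc_subtype"] == sub

    def test_pc_subtype_invariant(self, rng):
        """pc_subtype != not_a_PC implies lineage == PC."""
        panel = default_panel()
        pos = pd.DataFrame(
            rng.uniform(size=(500, 62)) < 0.5, columns=panel.gateable_names
        )
        labels = classify_cells(pos)
        typed = labels["pc_subtype"] != "not_a_PC"
        assert (labels.loc[typed, "lineage"] == "PC").all()
        assert (labels.loc[~typed, "lineage"] != "PC").all()


class TestFractions:
    def _labels(self, lineages, subtypes=None):
        return pd.DataFrame(
            {
                "lineage": lineages,
                "pc_subtype": subtypes or ["not_a_PC"] * len(lineages),
            }
        )

    def test_marker_fraction_arithmetic(self, panel):
        n_vim, n_pos = 40, 10
        pos = pd.DataFrame(False, index=range(n_vim), columns=panel.gateable_names)
        pos.loc[: n_pos - 1, "CD19"] = True
        labels = self._labels(["LP_immune"] * n_vim)
        frac = marker_fractions(labels, pos, pd.Series(["P1"] * n_vim))
        assert frac.loc["P1", "CD19"] == 25.0

    def test_marker_positive_everywhere_is_100(self, panel):
        pos = pd.DataFrame(False, index=range(5), columns=panel.gateable_names)
        pos["CD38"] = True
        labels = self._labels(["LP_immune"] * 5)
        frac = marker_fractions(labels, pos, pd.Series(["P1"] * 5))
        assert frac.loc["P1", "CD38"] == 100.0

    def test_no_vim_cells_reported_missing_not_zero(self, panel):
        pos = pd.DataFrame(True, index=range(3), columns=panel.gateable_names)
        labels = self._labels(["non_LP"] * 3)
        with pytest.warns(UserWarning, match="no Vim"):
            frac = marker_fractions(labels, pos, pd.Series(["P1"] * 3))
        assert frac.loc["P1"].isna().all()

    def test_subtype_fraction_arithmetic(self):
        subs = ["CD19+CD45+"] * 5 + ["CD19-CD45+"] * 3 + ["CD19-CD45-"] * 2
        labels = self._labels(["PC"] * 10, subs)
        frac = pc_subtype_fractions(labels, pd.Series(["P1"] * 10))
        assert frac.loc["P1"].tolist() == [50.0, 30.0, 20.0, 0.0]

    def test_single_subtype_is_100(self):
        labels = self._labels(["PC"] * 4, ["other"] * 4)
        frac = pc_subtype_fractions(labels, pd.Series(["P1"] * 4))
        assert frac.loc["P1", "other"] == 100.0
        assert frac.loc["P1"].sum() == 100.0

    def test_fractions_sum_to_100_and_permutation_invariant(self, rng):
        n = 200
        subs = rng.choice(PC_SUBTYPES, size=n)
        labels = self._labels(["PC"] * n, list(subs))
        pids = pd.Series(rng.choice(["P1", "P2"], size=n))
        frac = pc_subtype_fractions(labels, pids)
        np.testing.assert_allclose(frac.sum(axis=1), 100.0)
        perm = rng.permutation(n)
        frac2 = pc_subtype_fractions(
            labels.iloc[perm].reset_index(drop=True),
            pids.iloc[perm].reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(frac.sort_index(), frac2.sort_index())

    def test_no_pcs_reported_missing(self):
        labels = self._labels(["LP_immune"] * 3)
        with pytest.warns(UserWarning, match="no PCs"):
            frac = pc_subtype_fractions(labels, pd.Series(["P1"] * 3))
        assert frac.loc["P1"].isna().all()


class TestRelativeAbundance:
    def test_control_median_set_to_1(self):
        values = pd.Series([1.0, 2.0, 3.0, 3.0], index=["a", "b", "c", "d"])
        scaled = relative_abundance(values, [True, True, True, False])
        assert scaled.tolist() == [0.5, 1.0, 1.5, 1.5]

    def test_identical_groups_have_median_1(self):
        values = pd.Series([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
        scaled = relative_abundance(values, [True] * 3 + [False] * 3)
        assert np.median(scaled[:3]) == 1.0
        assert np.median(scaled[3:]) == 1.0

    def test_zero_control_median_is_error(self):
        with pytest.raises(ValidationError, match="median is 0"):
            relative_abundance(pd.Series([0.0, 0.0, 5.0]), [True, True, False])

    def test_empty_control_is_error(self):
        with pytest.raises(ValidationError, match="control group is empty"):
            relative_abundance(pd.Series([1.0]), [False])


class TestSubtypeMarkerSummary:
    def _setup(self, panel):
        # two PCs of the reference subtype, two terminal PCs
        rows = [
            {"Vimentin": 500, "CD138": 200, "CD19": 500, "CD45": 500},
            {"Vimentin": 500, "CD138": 200, "CD19": 500, "CD45": 500, "Ki-67": 500},
            {"Vimentin": 500, "CD138": 180},
            {"Vimentin": 500, "CD138": 180},
        ]
        cells = make_cells(panel, rows)
        from sscpheno import call_positivity

        pos = call_positivity(cells)
        corrected = subtract_isotype_background(cells)
        labels = classify_cells(pos)
        return corrected, pos, labels

    def test_reference_normalisation(self, panel):
        corrected, pos, labels = self._setup(panel)
        out = subtype_marker_summary(
            corrected, pos, labels, markers=["CD138"], reference="CD19+CD45+"
        )
        by = out.set_index("pc_subtype")
        assert by.loc["CD19+CD45+", "rel_median_level"] == 1.0
        assert by.loc["CD19-CD45-", "rel_median_level"] == pytest.approx(180 / 200)

    def test_single_cell_median_is_that_cell(self, panel):
        rows = [{"Vimentin": 500, "CD138": 321.0, "CD19": 500, "CD45": 500}]
        cells = make_cells(panel, rows)
        from sscpheno import call_positivity

        pos = call_positivity(cells)
        labels = classify_cells(pos)
        out = subtype_marker_summary(
            subtract_isotype_background(cells), pos, labels, markers=["CD138"]
        )
        assert out.loc[0, "median_level"] == 321.0

    def test_pct_positive_from_positivity(self, panel):
        corrected, pos, labels = self._setup(panel)
        out = subtype_marker_summary(corrected, pos, labels, markers=["Ki-67"])
        by = out.set_index("pc_subtype")
        assert by.loc["CD19+CD45+", "pct_positive"] == 50.0
        assert by.loc["CD19-CD45-", "pct_positive"] == 0.0

    def test_empty_subtype_missing_not_zero(self, panel):
        corrected, pos, labels = self._setup(panel)
        out = subtype_marker_summary(corrected, pos, labels, markers=["CD138"])
        assert "CD19-CD45+" not in set(out["pc_subtype"])


class TestSelectPhenotypingTargets:
    def test_default_exclusions_leave_49_targets(self, panel):
        assert len(select_phenotyping_targets(panel)) == 49

    def test_empty_exclusions_keep_all_gateable(self, panel):
        assert select_phenotyping_targets(panel, []) == panel.gateable_names

    def test_unknown_exclusion_name_is_error(self, panel):
        with pytest.raises(ConfigurationError, match="CD3x"):
            select_phenotyping_targets(panel, ["CD3x"])

    def test_controls_never_retained(self, panel):
        kept = select_phenotyping_targets(panel)
        assert not set(kept) & set(panel.control_names)
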