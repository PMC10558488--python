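import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cofactomics.tables_io import (
    ConcentrationMatrix,
    SampleDesign,
    drop_all_missing_entities,
    drop_incomplete_proteins,
    group_fold_change,
    impute_half_minimum,
    median_ratio_normalize,
    read_concentration_table,
    welch_volcano,
    write_fold_change_table,
    read_fold_change_table,
)


class TestReading:
    def test_csv_parse_and_shape(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,s1,s2\na,1,2\nb,3,4\n")
        m = read_concentration_table(p, unit="mM", entity_kind="metabolite")
        assert m.entity_ids == ["a", "b"]
        assert m.sample_ids == ["s1", "s2"]
        assert m.data.loc["b", "s2"] == 4

    @pytest.mark.parametrize("token", ["NA", "NaN", ""])
    def test_missing_tokens_become_nan(self, tmp_path, token):
        p = tmp_path / "m.csv"
        p.write_text(f"id,s1,s2\na,{token},2\n")
        m = read_concentration_table(p, unit="mM", entity_kind="metabolite")
        assert np.isnan(m.data.loc["a", "s1"])

    def test_duplicate_entity_errors_with_name(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,s1\nGly,1\nGly,2\n")
        with pytest.raises(ValueError, match="Gly"):
            read_concentration_table(p, unit="mM", entity_kind="metabolite")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ConcentrationMatrix(
                data=pd.DataFrame({"s": [1.0]}, index=["a"]), unit="furlongs", entity_kind="protein"
            )

    def test_negative_values_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,s1\na,-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_concentration_table(p, unit="mM", entity_kind="metabolite")

    def test_round_trip_preserves_values(self, toy_matrix, tmp_path):
        p = tmp_path / "rt.tsv"
        toy_matrix.data.rename_axis("id").to_csv(p, sep="\t")
        back = read_concentration_table(p, unit="umol_per_g", entity_kind="metabolite")
        pd.testing.assert_frame_equal(back.data, toy_matrix.data, check_names=False)


class TestMissingValueRules:
    def test_all_missing_entity_removed_others_kept(self):
        data = pd.DataFrame(
            {"s1": [np.nan, 1.0], "s2": [np.nan, np.nan]}, index=["gone", "kept"]
        )
        m = ConcentrationMatrix(data=data, unit="mM", entity_kind="metabolite")
        out = drop_all_missing_entities(m)
        assert out.entity_ids == ["kept"]

    def test_impute_uses_global_minimum_not_row_minimum(self):
        # row minima are 1 and 0.4; the imputed value must be 0.2 everywhere
        data = pd.DataFrame(
            {"s1": [1.0, 0.4], "s2": [np.nan, np.nan], "s3": [2.0, 0.9]},
            index=["a", "b"],
        )
        m = ConcentrationMatrix(data=data, unit="mM", entity_kind="metabolite")
        # independent brute-force scan over all present values
        present = [v for v in data.to_numpy().ravel() if np.isfinite(v)]
        expected = 0.5 * min(present)
        out = impute_half_minimum(m)
        assert out.data.loc["a", "s2"] == expected == 0.2
        assert out.data.loc["b", "s2"] == expected

    def test_impute_never_changes_present_values(self, toy_matrix):
        out = impute_half_minimum(toy_matrix)
        mask = toy_matrix.data.notna().to_numpy()
        assert (out.data.to_numpy()[mask] == toy_matrix.data.to_numpy()[mask]).all()
        assert out.data.notna().all().all()

    def test_impute_identity_when_complete(self, toy_matrix):
        complete = impute_half_minimum(toy_matrix)
        again = impute_half_minimum(complete)
        pd.testing.assert_frame_equal(again.data, complete.data)

    def test_impute_empty_matrix_errors(self):
        data = pd.DataFrame({"s1": [np.nan]}, index=["a"])
        m = ConcentrationMatrix(data=data, unit="mM", entity_kind="metabolite")
        with pytest.raises(ValueError):
            impute_half_minimum(m)

    def test_incomplete_proteins_dropped(self):
        data = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [np.nan, 2.0]}, index=["incomplete", "complete"]
        )
        m = ConcentrationMatrix(data=data, unit="intensity", entity_kind="protein")
        assert drop_incomplete_proteins(m).entity_ids == ["complete"]

    def test_all_incomplete_warns_and_empties(self):
        data = pd.DataFrame({"s1": [np.nan], "s2": [1.0]}, index=["a"])
        m = ConcentrationMatrix(data=data, unit="intensity", entity_kind="protein")
        with pytest.warns(UserWarning):
            out = drop_incomplete_proteins(m)
        assert len(out.entity_ids) == 0


class TestMedianRatioNormalize:
    def test_doubled_sample_rescaled_to_reference(self):
        data = pd.DataFrame(
            {"ref": [1.0, 2.0, 3.0], "x": [2.0, 4.0, 6.0]}, index=["a", "b", "c"]
        )
        m = ConcentrationMatrix(data=data, unit="intensity", entity_kind="protein")
        out, scales = median_ratio_normalize(m, "ref")
        assert scales["x"] == 2.0
        assert np.allclose(out.data["x"], out.data["ref"])

    def test_reference_scale_is_one(self, toy_matrix):
        complete = impute_half_minimum(toy_matrix)
        _, scales = median_ratio_normalize(complete, "s1")
        assert scales["s1"] == 1.0

    def test_median_of_ratios_oracle(self):
        # per-entity ratios to reference are {1, 2, 4}: scale = median = 2
        data = pd.DataFrame(
            {"ref": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 4.0]}, index=["a", "b", "c"]
        )
        m = ConcentrationMatrix(data=data, unit="intensity", entity_kind="protein")
        _, scales = median_ratio_normalize(m, "ref")
        assert scales["x"] == sorted([1.0, 2.0, 4.0])[1]

    def test_idempotent(self, toy_matrix):
        complete = impute_half_minimum(toy_matrix)
        once, _ = median_ratio_normalize(complete, "s1")
        _, scales = median_ratio_normalize(once, "s1")
        assert np.allclose(scales, 1.0)

    def test_zero_reference_entity_excluded_with_warning(self):
        data = pd.DataFrame({"ref": [0.0, 1.0, 1.0], "x": [5.0, 2.0, 2.0]}, index=list("abc"))
        m = ConcentrationMatrix(data=data, unit="intensity", entity_kind="protein")
        with pytest.warns(UserWarning, match="reference value 0"):
            _, scales = median_ratio_normalize(m, "ref")
        assert scales["x"] == 2.0


def _matrix_for(design, values_by_model):
    cols = {}
    for model, (exp_vals, ctl_vals) in values_by_model.items():
        for s, v in zip(design.samples_for(model, "experimental"), exp_vals):
            cols[s] = v
        for s, v in zip(design.samples_for(model, "control"), ctl_vals):
            cols[s] = v
    return ConcentrationMatrix(
        data=pd.DataFrame(cols, index=[f"e{i}" for i in range(len(next(iter(cols.values()))))]),
        unit="intensity",
        entity_kind="protein",
    )


class TestFoldChange:
    def test_ratio_of_group_means(self, two_arm_design):
        m = _matrix_for(
            two_arm_design,
            {"CRCA": ([[4.0], [4.0], [4.0]], [[2.0], [2.0], [2.0]]),
             "SEKI": ([[1.0], [1.0], [1.0]], [[1.0], [1.0], [1.0]])},
        )
        fc = group_fold_change(m, two_arm_design, "CRCA")
        assert fc.table.loc[0, "fc"] == 2.0
        assert fc.table.loc[0, "log2fc"] == 1.0
        fc2 = group_fold_change(m, two_arm_design, "SEKI")
        assert fc2.table.loc[0, "fc"] == 1.0
        assert fc2.table.loc[0, "log2fc"] == 0.0

    def test_proportional_matrix_recovers_constant(self, two_arm_design):
        rng = np.random.default_rng(0)
        ctl = rng.lognormal(size=(8, 3))
        c = 2.7
        cols = {}
        for k, s in enumerate(two_arm_design.samples_for("CRCA", "control")):
            cols[s] = ctl[:, k]
        for k, s in enumerate(two_arm_design.samples_for("CRCA", "experimental")):
            cols[s] = c * ctl[:, k]
        m = ConcentrationMatrix(
            data=pd.DataFrame(cols, index=[f"e{i}" for i in range(8)]),
            unit="intensity",
            entity_kind="protein",
        )
        fc = group_fold_change(m, two_arm_design, "CRCA")
        assert np.allclose(fc.table["fc"], c)

    def test_zero_control_mean_excluded(self, two_arm_design):
        cols = {s: [0.0] for s in two_arm_design.samples_for("CRCA", "control")}
        cols.update({s: [1.0] for s in two_arm_design.samples_for("CRCA", "experimental")})
        cols.update({s: [1.0] for s in two_arm_design.samples_for("SEKI", "control")})
        cols.update({s: [1.0] for s in two_arm_design.samples_for("SEKI", "experimental")})
        m = ConcentrationMatrix(
            data=pd.DataFrame(cols, index=["e0"]), unit="intensity", entity_kind="protein"
        )
        fc = group_fold_change(m, two_arm_design, "CRCA")
        assert fc.excluded == ("e0",)
        assert len(fc.table) == 0

    def test_missing_model_errors(self, toy_matrix, two_arm_design):
        with pytest.raises(ValueError):
            group_fold_change(toy_matrix, two_arm_design, "MEWO")

    def test_round_trip_tsv(self, two_arm_design, tmp_path):
        m = _matrix_for(
            two_arm_design,
            {"CRCA": ([[4.0], [4.0], [4.0]], [[2.0], [2.0], [2.0]]),
             "SEKI": ([[1.0], [1.0], [1.0]], [[1.0], [1.0], [1.0]])},
        )
        fc = group_fold_change(m, two_arm_design, "CRCA")
        p = tmp_path / "fc.tsv"
        write_fold_change_table(fc, p)
        back = read_fold_change_table(p)
        pd.testing.assert_frame_equal(back.table, fc.table)


class TestWelchVolcano:
    def test_identical_groups_p_is_one(self, two_arm_design):
        cols = {s: [3.0, 5.0] for s in two_arm_design.table["sample_id"]}
        m = ConcentrationMatrix(
            data=pd.DataFrame(cols, index=["e0", "e1"]), unit="intensity", entity_kind="protein"
        )
        fc = welch_volcano(m, two_arm_design, "CRCA")
        assert (fc.table["p"] == 1.0).all()

    def test_matches_hand_welch_formula(self, two_arm_design):
        a = np.array([1.0, 2.0, 3.5])
        b = np.array([4.0, 5.5, 7.0])
        cols = {}
        for v, s in zip(a, two_arm_design.samples_for("CRCA", "experimental")):
            cols[s] = [v]
        for v, s in zip(b, two_arm_design.samples_for("CRCA", "control")):
            cols[s] = [v]
        for s in two_arm_design.table["sample_id"]:
            cols.setdefault(s, [1.0])
        m = ConcentrationMatrix(
            data=pd.DataFrame(cols, index=["e0"]), unit="intensity", entity_kind="protein"
        )
        fc = welch_volcano(m, two_arm_design, "CRCA")
        # textbook Welch statistic and Welch-Satterthwaite df, by hand
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert fc.table.loc[0, "p"] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_different_means_p_zero(self, two_arm_design):
        cols = {s: [1.0] for s in two_arm_design.samples_for("CRCA", "control")}
        cols.update({s: [2.0] for s in two_arm_design.samples_for("CRCA", "experimental")})
        for s in two_arm_design.table["sample_id"]:
            cols.setdefault(s, [1.0])
        m = ConcentrationMatrix(
            data=pd.DataFrame(cols, index=["e0"]), unit="intensity", entity_kind="protein"
        )
        fc = welch_volcano(m, two_arm_design, "CRCA")
        assert fc.table.loc[0, "p"] == 0.0

    def test_requires_two_per_arm(self, two_arm_design):
        design = SampleDesign(
            table=two_arm_design.table[
                ~two_arm_design.table["sample_id"].isin(["CRCA_exp_1", "CRCA_exp_2"])
            ]
        )
        cols = {s: [1.0] for s in design.table["sample_id"]}
        m = ConcentrationMatrix(
            data=pd.DataFrame(cols, index=["e0"]), unit="intensity", entity_kind="protein"
        )
        with pytest.raises(ValueError, match=">=2"):
            welch_volcano(m, design, "CRCA")
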