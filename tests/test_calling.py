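import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from mosaicloy import (
    CountMatrix,
    DatasetProfile,
    LOYCaller,
    MSYPanel,
    ValidationError,
    assign_loy_calls,
    call_loy_cells,
    filter_min_cells,
    filter_min_patients,
    infer_donor_sex,
    msy_fraction_per_cell,
    pooled_pct_loy,
    summarize_pct_loy,
)


def single_cell_matrix(counts: dict) -> CountMatrix:
    genes = list(counts)
    values = np.array([[counts[g]] for g in genes])
    return CountMatrix(sp.csr_matrix(values), genes, ["c1"])


class TestMsyFraction:
    def test_direct_ratio(self):
        cm = single_cell_matrix({"RPS4Y1": 2, "ACTB": 8})
        with pytest.warns(UserWarning, match="dropped"):
            frac = msy_fraction_per_cell(cm)
        assert frac.iloc[0] == pytest.approx(0.2)

    def test_zero_panel_counts_give_zero(self, toy_matrix):
        with pytest.warns(UserWarning):
            frac = msy_fraction_per_cell(toy_matrix)
        assert frac["c3"] == 0.0

    def test_zero_total_cell_warns_and_yields_zero(self):
        values = np.array([[0, 1], [0, 3]])
        cm = CountMatrix(sp.csr_matrix(values), ["RPS4Y1", "ACTB"], ["c1", "c2"])
        with pytest.warns(UserWarning):
            frac = msy_fraction_per_cell(cm)
        assert frac["c1"] == 0.0

    def test_positive_for_all_nonloy_cells_without_dropout(self, zero_dropout_dataset):
        _, matrix, cells = zero_dropout_dataset
        frac = msy_fraction_per_cell(matrix)
        non_loy = cells.loc[~cells["truth_loy"], "cell_id"]
        assert (frac[non_loy] > 0).all()

    def test_no_panel_gene_present_is_config_error(self):
        cm = single_cell_matrix({"ACTB": 5})
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                call_loy_cells(cm)


class TestCallRule:
    def test_single_expressed_gene_means_nonloy(self, toy_matrix):
        with pytest.warns(UserWarning):
            calls = call_loy_cells(toy_matrix)
        assert calls["c2"] == "nonLOY"  # only EIF1AY = 1

    def test_all_zero_panel_means_loy(self, toy_matrix):
        with pytest.warns(UserWarning):
            calls = call_loy_cells(toy_matrix)
        assert calls["c3"] == "LOY"

    def test_calls_recover_truth_exactly_without_dropout(self, zero_dropout_dataset):
        _, matrix, cells = zero_dropout_dataset
        calls = call_loy_cells(matrix)
        truth = cells.set_index("cell_id")["truth_loy"]
        assert ((calls == "LOY") == truth.loc[calls.index]).all()

    def test_invariant_to_gene_and_cell_order(self, toy_matrix):
        with pytest.warns(UserWarning):
            calls = call_loy_cells(toy_matrix)
        rng = np.random.default_rng(0)
        g_perm = rng.permutation(toy_matrix.n_genes)
        c_perm = rng.permutation(toy_matrix.n_cells)
        shuffled = CountMatrix(
            toy_matrix.values[g_perm][:, c_perm],
            toy_matrix.gene_ids[g_perm],
            toy_matrix.cell_ids[c_perm],
        )
        with pytest.warns(UserWarning):
            calls2 = call_loy_cells(shuffled)
        assert calls2.sort_index().equals(calls.sort_index())

    def test_zero_fraction_iff_loy_with_full_panel(self, default_dataset):
        _, matrix, _ = default_dataset
        calls = call_loy_cells(matrix)
        frac = msy_fraction_per_cell(matrix)
        np.testing.assert_array_equal(frac.to_numpy() == 0, calls.to_numpy() == "LOY")

    def test_estimator_validates_input(self):
        caller = LOYCaller()
        with pytest.raises(TypeError):
            caller.fit(np.zeros((2, 2)))


class TestSexInference:
    def test_all_zero_msy_donor_is_female(self):
        values = np.zeros((6, 3), dtype=int)
        values[0] += 0
        cm = CountMatrix(sp.csr_matrix(values),
                         ["RPS4Y1", "ZFY", "USP9Y", "DDX3Y", "KDM5D", "EIF1AY"],
                         ["c1", "c2", "c3"])
        cells = pd.DataFrame({"cell_id": ["c1", "c2", "c3"], "donor_id": "D1",
                              "tissue": "tumor"})
        sexes = infer_donor_sex(cm, cells)
        assert sexes.loc[sexes["donor_id"] == "D1", "sex"].item() == "female"

    def test_single_expressing_cell_makes_donor_male(self):
        values = np.zeros((6, 2), dtype=int)
        values[3, 0] = 1  # DDX3Y in one cell
        cm = CountMatrix(sp.csr_matrix(values),
                         ["RPS4Y1", "ZFY", "USP9Y", "DDX3Y", "KDM5D", "EIF1AY"],
                         ["c1", "c2"])
        cells = pd.DataFrame({"cell_id": ["c1", "c2"], "donor_id": "D1",
                              "tissue": "blood"})
        sexes = infer_donor_sex(cm, cells)
        assert sexes["sex"].item() == "male"

    def test_mixed_cohort_sexes_recovered(self, default_dataset):
        config, matrix, cells = default_dataset
        sexes = infer_donor_sex(matrix, cells).set_index("donor_id")["sex"]
        expected = {f"D{i + 1:02d}": s for i, s in enumerate(config.donor_sexes)}
        assert dict(sexes) == expected

    def test_donor_without_cells_excluded_with_warning(self, toy_matrix):
        cells = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3", "missing"],
            "donor_id": ["D1", "D1", "D1", "D2"],
            "tissue": "tumor",
        })
        with pytest.warns(UserWarning, match="D2"):
            sexes = infer_donor_sex(toy_matrix, cells)
        assert list(sexes["donor_id"]) == ["D1"]

    def test_female_donor_cells_left_unassigned(self, default_dataset):
        _, matrix, cells = default_dataset
        called = assign_loy_calls(matrix, cells)
        female = called["donor_sex"] == "female"
        assert (called.loc[female, "loy_call"] == "unassigned").all()
        assert set(called.loc[~female, "loy_call"]) <= {"LOY", "nonLOY"}


class TestSummaries:
    def test_published_pooled_counts(self):
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(498)],
            "donor_id": "D1", "tissue": "tumor", "cell_type": "Treg",
            "loy_call": ["LOY"] * 101 + ["nonLOY"] * 397,
        })
        summary = summarize_pct_loy(cells)
        row = summary.iloc[0]
        assert (row["n_cells"], row["n_loy"]) == (498, 101)
        assert row["pct_loy"] == pytest.approx(100 * 101 / 498)
        assert round(row["pct_loy"], 2) == 20.28

    def test_group_without_loy_is_zero(self):
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(10)],
            "donor_id": "D1", "tissue": "UM", "cell_type": "Th",
            "loy_call": "nonLOY",
        })
        assert summarize_pct_loy(cells)["pct_loy"].item() == 0.0

    def test_empty_grouping_yields_empty_frame(self):
        cells = pd.DataFrame(columns=["cell_id", "donor_id", "tissue",
                                      "cell_type", "loy_call"])
        assert summarize_pct_loy(cells).empty

    def test_pooled_pct_matches_row_scan(self, default_dataset):
        _, matrix, cells = default_dataset
        called = assign_loy_calls(matrix, cells)
        summary = summarize_pct_loy(called)
        # brute-force row scan over the cell table
        rows = called[called["loy_call"].isin(["LOY", "nonLOY"])]
        expected = 100.0 * sum(r == "LOY" for r in rows["loy_call"]) / len(rows)
        assert pooled_pct_loy(summary) == pytest.approx(expected)
        assert summary["n_cells"].sum() == len(rows)

    def test_loy_fraction_recovered_within_99pct_binomial_ci(self):
        from mosaicloy import SimulationConfig, generate_expression_dataset
        config = SimulationConfig(
            n_donors=1, tissues=("tumor",), n_cells_per_donor_tissue=6000,
            cell_type_props={"Treg": 0.25, "Th": 0.25, "CTL": 0.25, "other": 0.25},
            msy_dropout=0.0, seed=31,
        )
        matrix, cells = generate_expression_dataset(config)
        called = assign_loy_calls(matrix, cells)
        summary = summarize_pct_loy(called, group_keys=("tissue", "cell_type"))
        for ct, p_true in (("Treg", 0.22), ("Th", 0.11), ("CTL", 0.14)):
            row = summary[summary["cell_type"] == ct].iloc[0]
            assert row["n_cells"] >= 1000
            lo, hi = scipy.stats.binom.interval(0.99, row["n_cells"], p_true)
            assert lo <= row["n_loy"] <= hi


class TestFilters:
    @pytest.mark.parametrize(
        "n_cells,min_cells,kept",
        [(14, 15, False), (15, 15, True), (49, 50, False), (50, 50, True)],
    )
    def test_strictly_lower_removal(self, n_cells, min_cells, kept):
        summaries = pd.DataFrame(
            [{"donor_id": "D1", "tissue": "tumor", "cell_type": "Treg",
              "n_cells": n_cells, "n_loy": 1, "pct_loy": 100 / n_cells}]
        )
        profile = DatasetProfile(min_group_cells=min_cells)
        out = filter_min_cells(summaries, profile)
        assert (len(out) == 1) is kept

    def test_min_patients_boundary(self):
        rows = []
        for c, n_donors in (("A", 3), ("B", 4)):
            for d in range(n_donors):
                rows.append({"cancer_type": c, "donor_id": f"{c}{d}",
                             "cell_type": "Treg", "n_cells": 100, "n_loy": 5,
                             "pct_loy": 5.0})
        out = filter_min_patients(pd.DataFrame(rows), DatasetProfile())
        assert set(out["cancer_type"]) == {"B"}

    def test_cancer_survival_count(self):
        rows = []
        for c in range(1, 9):  # cancers with 1..8 donors
            for d in range(c):
                rows.append({"cancer_type": f"C{c}", "donor_id": f"C{c}_D{d}",
                             "n_cells": 60, "n_loy": 3, "pct_loy": 5.0})
        out = filter_min_patients(pd.DataFrame(rows), DatasetProfile())
        assert out["cancer_type"].nunique() == 5

    def test_missing_cancer_key_errors(self):
        with pytest.raises(ValidationError, match="cancer_type"):
            filter_min_patients(pd.DataFrame({"donor_id": ["D1"], "n_cells": [99]}),
                                DatasetProfile())
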