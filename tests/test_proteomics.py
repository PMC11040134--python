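import numpy as np
import pandas as pd
import pytest

from mitoribo.proteomics import (
    annotate_mito,
    classify_protein_change,
    correct_isotope_impurities,
    dotplot_table,
    normalize_channels,
    protein_statistics,
    rollup_proteins,
)
from mitoribo.simulate import (
    TmtParams,
    TruthTable,
    default_plex_design,
    impurity_matrix,
    simulate_tmt_experiment,
)


def _table(values, channels=("126", "127N"), proteins=None):
    values = np.atleast_2d(values)
    df = pd.DataFrame(values, columns=list(channels))
    df.insert(0, "protein_id", proteins or [f"P{i}" for i in range(len(df))])
    df.insert(0, "peptide_id", [f"pep{i}" for i in range(len(df))])
    return df


class TestImpurityCorrection:
    def test_identity_matrix_leaves_table_unchanged(self):
        table = _table([[100.0, 50.0]])
        imp = pd.DataFrame(np.eye(2), index=["126", "127N"], columns=["126", "127N"])
        out = correct_isotope_impurities(table, imp)
        assert np.allclose(out[["126", "127N"]], table[["126", "127N"]])

    def test_two_channel_hand_solution(self):
        """10% spill each way, a=100, b=0: observed (90, 10) recovers (100, 0)."""
        imp = pd.DataFrame([[0.9, 0.1], [0.1, 0.9]],
                           index=["126", "127N"], columns=["126", "127N"])
        table = _table([[90.0, 10.0]])
        out = correct_isotope_impurities(table, imp)
        assert out.loc[0, "126"] == pytest.approx(100.0, abs=1e-9)
        assert out.loc[0, "127N"] == pytest.approx(0.0, abs=1e-9)

    def test_all_missing_row_passes_through(self):
        imp = pd.DataFrame([[0.9, 0.1], [0.1, 0.9]],
                           index=["126", "127N"], columns=["126", "127N"])
        table = _table([[np.nan, np.nan]])
        out = correct_isotope_impurities(table, imp)
        assert out[["126", "127N"]].isna().all().all()

    def test_forward_mixing_round_trip(self, rng):
        """Applying the label mixing then the correction recovers the input."""
        imp = impurity_matrix(16, 0.02)
        true = rng.lognormal(10, 1, size=(40, 16))
        observed = true @ imp.to_numpy()
        table = _table(observed, channels=imp.columns)
        out = correct_isotope_impurities(table, imp)
        assert np.allclose(out[imp.columns].to_numpy(), true, rtol=1e-8)

    def test_missingness_does_not_leak_across_proteins(self):
        imp = impurity_matrix(2, 0.0).iloc[:2, :2]
        imp.index = imp.columns = ["126", "127N"]
        t1 = _table([[100.0, 50.0], [80.0, 40.0]])
        t2 = t1.copy()
        t2.loc[1, "126"] = np.nan
        o1 = correct_isotope_impurities(t1, imp)
        o2 = correct_isotope_impurities(t2, imp)
        assert np.allclose(o1.loc[0, ["126", "127N"]].astype(float),
                           o2.loc[0, ["126", "127N"]].astype(float))


class TestNormalization:
    def test_equal_median_channels_unchanged_up_to_constant(self):
        table = _table([[4.0, 4.0], [16.0, 16.0], [64.0, 64.0]])
        out = normalize_channels(table, min_values=1)
        expected = np.log2(table[["126", "127N"]])
        assert np.allclose(out[["126", "127N"]], expected)

    def test_doubled_channel_shifts_down_by_one(self):
        base = np.array([[4.0, 8.0], [16.0, 32.0], [64.0, 128.0]])
        out = normalize_channels(_table(base), min_values=1)
        log2 = out[["126", "127N"]].to_numpy()
        assert np.allclose(log2[:, 1] - log2[:, 0], 0.0)

    def test_loading_imbalance_equalizes_medians(self, rng):
        factors = np.exp(rng.uniform(-1, 1, size=6))
        base = rng.lognormal(10, 1, size=(200, 6))
        channels = ["126", "127N", "127C", "128N", "128C", "129N"]
        out = normalize_channels(_table(base * factors, channels=channels))
        med = out[channels].median()
        assert np.allclose(med, med.iloc[0], atol=1e-9)


class TestRollup:
    def test_single_peptide_protein_identical(self):
        table = _table([[1.0, 2.0]], proteins=["A"])
        out = rollup_proteins(table)
        assert out.loc["A", ["126", "127N"]].tolist() == [1.0, 2.0]

    def test_two_peptides_averaged(self):
        table = _table([[4.0, 4.0], [6.0, 6.0]], proteins=["A", "A"])
        out = rollup_proteins(table)
        assert out.loc["A", "126"] == 5.0
        assert out.loc["A", "n_peptides"] == 2

    def test_matches_groupby_mean_oracle(self, rng):
        n = 50
        table = _table(rng.normal(10, 2, size=(n, 2)),
                       proteins=[f"P{i % 7}" for i in range(n)])
        out = rollup_proteins(table)
        oracle = table.groupby("protein_id")[["126", "127N"]].mean()
        assert np.allclose(out[["126", "127N"]], oracle)

    def test_shared_peptides_dropped_by_default(self):
        table = pd.DataFrame({
            "peptide_id": ["shared", "shared", "own"],
            "protein_id": ["A", "B", "A"],
            "126": [1.0, 1.0, 5.0], "127N": [1.0, 1.0, 7.0]})
        out = rollup_proteins(table)
        assert out.loc["A", "126"] == 5.0
        assert "B" not in out.index


class TestProteinStatistics:
    def _run(self, shifts=None, params=None, seed=0):
        ids = [f"P{i}" for i in range(30)]
        truth = TruthTable.null(ids)
        if shifts:
            truth.set_protein_shift(*shifts)
        params = params or TmtParams(impurity_spill=0.0, dropout_scale=0.0)
        pep, plex, _ = simulate_tmt_experiment(ids, truth, params=params, seed=seed)
        rolled = rollup_proteins(normalize_channels(pep))
        return protein_statistics(rolled, plex), ids

    def test_null_proteins_do_not_pass_gate(self):
        stats, _ = self._run()
        assert stats["passes_gate_het"].sum() + stats["passes_gate_homo"].sum() <= 2

    def test_planted_homo_shift_detected_with_accurate_fc(self):
        stats, ids = self._run(shifts=(["P0", "P1", "P2"], 0.0, -1.0))
        for p in ("P0", "P1", "P2"):
            assert stats.loc[p, "passes_gate_homo"]
            assert stats.loc[p, "log2fc_homo"] == pytest.approx(-1.0, abs=0.25)

    @pytest.mark.parametrize("variant", ["welch", "student"])
    def test_rowwise_ttests_match_scipy(self, variant, rng):
        from scipy import stats as sps
        from mitoribo.proteomics import _pairwise_t_pvalues
        a = rng.normal(size=(40, 5))
        b = rng.normal(size=(40, 5))
        a[rng.random(a.shape) < 0.15] = np.nan
        p = _pairwise_t_pvalues(a, b, variant)
        for i in range(40):
            ai, bi = a[i][~np.isnan(a[i])], b[i]
            if len(ai) < 2:
                assert np.isnan(p[i])
                continue
            ref = sps.ttest_ind(ai, bi, equal_var=(variant == "student"))
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_bh_q_dominates_anova_p(self):
        stats, _ = self._run(shifts=(["P0"], 1.0, 1.0))
        ok = stats["anova_p"].notna()
        assert (stats.loc[ok, "bh_q"] >= stats.loc[ok, "anova_p"] - 1e-12).all()


class TestAnnotateAndPlot:
    def test_case_insensitive_mito_match(self):
        records = pd.DataFrame(index=["Mrpl12", "Gapdh"])
        out = annotate_mito(records, ["MRPL12", "mt-Nd1"])
        assert out.loc["Mrpl12", "mito_flag"]
        assert not out.loc["Gapdh", "mito_flag"]

    def test_duplicate_list_entries_idempotent(self):
        records = pd.DataFrame(index=["Mrpl12"])
        a = annotate_mito(records, ["Mrpl12"])
        b = annotate_mito(records, ["Mrpl12", "Mrpl12"])
        assert a.equals(b)

    def test_dotplot_table_shape_and_values(self):
        stats = pd.DataFrame({
            "ttest_p_het": [0.01, 1.0], "ttest_p_homo": [0.5, np.nan],
            "log2fc_het": [1.0, -1.0], "log2fc_homo": [0.5, 0.0]},
            index=["A", "B"])
        table = dotplot_table(stats)
        assert len(table) == 4
        row = table[(table.protein_id == "A")
                    & (table.comparison == "het_vs_control")].iloc[0]
        assert row["neg_log10_p"] == pytest.approx(2.0)
        row = table[(table.protein_id == "B")
                    & (table.comparison == "het_vs_control")].iloc[0]
        assert row["neg_log10_p"] == 0.0
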