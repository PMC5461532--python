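"""Design construction, Type II ANOVA, partial eta squared, Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fracres import (
    ValidationError,
    anova_type2,
    build_design,
    partial_eta_squared,
    tukey_from_design,
    tukey_hsd,
)
from fracres.anova import (
    split_regulation_response,
    studentized_range_crit,
    studentized_range_sf,
)

from oracles import brute_force_f_stats, brute_force_type2


def random_design(rng) -> pd.DataFrame:
    """A balanced 36-row cell-mean design with random responses."""
    rows = []
    for hi in ("Z1", "Z2", "Z3"):
        for t in range(1, 7):
            for b in ("HighExp", "LowExp"):
                rows.append((hi, f"{hi}{t}", b, rng.uniform(0, 3), 10))
    return pd.DataFrame(
        rows, columns=["GOf", "term", "ExpQ", "mean_retention", "n_genes"]
    )


def records_frame(cells: dict) -> pd.DataFrame:
    rows = []
    for (low, b), indices in cells.items():
        for i, idx in enumerate(indices):
            rows.append((f"g_{low}_{b}_{i}", "sp", f"f{i}", idx, low[:2], low, 1.0, b))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "species",
            "family_id",
            "retention_index",
            "high_code",
            "low_code",
            "expression_score",
            "bin",
        ],
    )


class TestBuildDesign:
    def test_cell_means(self):
        records = records_frame(
            {
                ("Z11", "HighExp"): [3, 1],
                ("Z11", "LowExp"): [0, 2],
                ("Z21", "HighExp"): [2],
                ("Z21", "LowExp"): [0],
            }
        )
        design = build_design(records)
        got = design.set_index(["term", "ExpQ"])["mean_retention"]
        assert got[("Z11", "HighExp")] == 2.0
        assert got[("Z11", "LowExp")] == 1.0
        assert got[("Z21", "HighExp")] == 2.0
        assert got[("Z21", "LowExp")] == 0.0
        assert design["n_genes"].sum() == 6

    def test_full_scheme_gives_36_rows(self, small_sim, default_scheme):
        from fracres.pipeline import records_from_simulation

        design = build_design(records_from_simulation(small_sim), scheme=default_scheme)
        assert len(design) == 36
        assert design.groupby("GOf").size().tolist() == [12, 12, 12]

    def test_constant_response_constant_cells(self):
        records = records_frame(
            {(low, b): [2, 2, 2] for low in ("Z11", "Z12") for b in ("HighExp", "LowExp")}
        )
        design = build_design(records)
        assert (design["mean_retention"] == 2.0).all()

    def test_empty_cell_is_error_naming_cell(self, default_scheme):
        records = records_frame({("Z11", "HighExp"): [1], ("Z11", "LowExp"): [2]})
        with pytest.raises(ValidationError, match="Z12"):
            build_design(records, scheme=default_scheme)


class TestPartialEtaSquared:
    def test_printed_worked_examples(self):
        assert partial_eta_squared(0.1211, 1.171) == pytest.approx(0.0937, abs=5e-4)
        assert partial_eta_squared(36.1933, 1.171) == pytest.approx(0.96865, abs=5e-4)

    def test_null_effect_is_zero(self):
        assert partial_eta_squared(0.0, 1.3) == 0.0

    def test_both_zero_flagged_missing(self):
        assert np.isnan(partial_eta_squared(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            partial_eta_squared(-0.1, 1.0)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0), st.floats(0.01, 10.0))
    def test_monotone_in_effect_ss(self, ss_a, bump, ss_res):
        assert partial_eta_squared(ss_a + bump, ss_res) >= partial_eta_squared(
            ss_a, ss_res
        )


class TestAnovaType2:
    def test_matches_brute_force_least_squares(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            design = random_design(rng)
            res = anova_type2(design)
            ss_g, ss_e, ss_i, ss_r = brute_force_type2(design)
            assert res["GOf"]["sum_sq"] == pytest.approx(ss_g, rel=1e-8)
            assert res["ExpQ"]["sum_sq"] == pytest.approx(ss_e, rel=1e-8)
            assert res["GOf:ExpQ"]["sum_sq"] == pytest.approx(ss_i, rel=1e-8)
            assert res["Residual"]["sum_sq"] == pytest.approx(ss_r, rel=1e-8)

    def test_type_i_ii_iii_coincide_on_balanced_design(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(17)
        design = random_design(rng)
        res2 = anova_type2(design)
        t1a = anova_lm(smf.ols("mean_retention ~ C(GOf) * C(ExpQ)", design).fit(), typ=1)
        t1b = anova_lm(smf.ols("mean_retention ~ C(ExpQ) * C(GOf)", design).fit(), typ=1)
        t3 = anova_lm(
            smf.ols("mean_retention ~ C(GOf, Sum) * C(ExpQ, Sum)", design).fit(), typ=3
        )
        assert res2["GOf"]["sum_sq"] == pytest.approx(t1a.loc["C(GOf)", "sum_sq"], rel=1e-8)
        assert res2["GOf"]["sum_sq"] == pytest.approx(t1b.loc["C(GOf)", "sum_sq"], rel=1e-8)
        assert res2["GOf"]["sum_sq"] == pytest.approx(t3.loc["C(GOf, Sum)", "sum_sq"], rel=1e-8)
        assert res2["ExpQ"]["sum_sq"] == pytest.approx(t1a.loc["C(ExpQ)", "sum_sq"], rel=1e-8)
        assert res2["ExpQ"]["sum_sq"] == pytest.approx(t3.loc["C(ExpQ, Sum)", "sum_sq"], rel=1e-8)

    def test_ss_additivity_on_balanced_design(self):
        rng = np.random.default_rng(23)
        design = random_design(rng)
        res = anova_type2(design)
        total = float(
            ((design["mean_retention"] - design["mean_retention"].mean()) ** 2).sum()
        )
        assert res.table.loc[["GOf", "ExpQ", "GOf:ExpQ", "Residual"], "sum_sq"].sum() == pytest.approx(
            total, rel=1e-10
        )

    def test_constant_response(self):
        design = random_design(np.random.default_rng(1))
        design["mean_retention"] = 2.0
        res = anova_type2(design)
        for term in ("GOf", "ExpQ", "GOf:ExpQ"):
            assert res[term]["sum_sq"] == pytest.approx(0.0, abs=1e-20)
            assert res[term]["partial_eta_sq"] == 0.0
            assert res[term]["F_value"] == 0.0

    def test_residual_df_matches_cell_count(self):
        design = random_design(np.random.default_rng(2))
        res = anova_type2(design)
        assert res.residual_df == 30  # 36 rows - 6 model params
        res4 = anova_type2(design, gof_levels=4)
        assert res4["GOf"]["df"] == 3
        assert res4.residual_df == 28

    def test_parametric_p_matches_permutation_null(self):
        """The GOf F-test p-value agrees with a permutation distribution
        of F over shuffled responses (within Monte-Carlo error)."""
        rng = np.random.default_rng(99)
        design = random_design(rng)
        design["mean_retention"] = rng.normal(1.5, 0.4, size=36)
        res = anova_type2(design)
        f_obs, _, _ = brute_force_f_stats(design)
        assert f_obs == pytest.approx(res["GOf"]["F_value"], rel=1e-8)
        n_perm = 5000
        count = 0
        shuffled = design.copy()
        y = design["mean_retention"].to_numpy().copy()
        for _ in range(n_perm):
            rng.shuffle(y)
            shuffled["mean_retention"] = y
            f_perm, _, _ = brute_force_f_stats(shuffled)
            count += f_perm >= f_obs
        p_perm = (count + 1) / (n_perm + 1)
        p_param = res["GOf"]["p_value"]
        se = np.sqrt(p_param * (1 - p_param) / n_perm)
        assert abs(p_perm - p_param) <= 4 * se + 1e-3

    def test_split_regulation_response_levels(self):
        design = random_design(np.random.default_rng(3))
        recoded = split_regulation_response(design)
        assert set(recoded["GOf"]) == {"Z1", "Z2", "Z3R", "Z3S"}
        assert (recoded.loc[recoded["term"] == "Z31", "GOf"] == "Z3R").all()
        assert (recoded.loc[recoded["term"] == "Z36", "GOf"] == "Z3S").all()


class TestStudentizedRange:
    @pytest.mark.parametrize("k,df", [(2, 30), (3, 30), (3, 33), (4, 12), (3, 5)])
    def test_sf_matches_scipy(self, k, df):
        q = np.array([0.3, 1.0, 2.2, 3.5, 5.0])
        ours = studentized_range_sf(q, k, df)
        ref = stats.studentized_range.sf(q, k, df)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_crit_matches_scipy_ppf(self):
        ours = studentized_range_crit(0.95, 3, 30.0)
        ref = stats.studentized_range.ppf(0.95, 3, 30)
        assert ours == pytest.approx(ref, rel=1e-6)


class TestTukey:
    def test_identical_groups_null(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        g = np.repeat(["a", "b", "c"], 4)
        res = tukey_hsd(y, g)
        assert (res["estimate"] == 0).all()
        assert (res["p_adjusted"] == 1.0).all()
        assert np.allclose(res["ci_low"], -res["ci_high"])

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=24)
        g = np.repeat(["a", "b"], 12)
        res = tukey_hsd(y, g)
        t_p = stats.ttest_ind(y[12:], y[:12], equal_var=True).pvalue
        assert res.loc[0, "p_adjusted"] == pytest.approx(t_p, abs=1e-6)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        y = rng.normal(loc=np.repeat([0.0, 0.4, 1.0], 12), scale=0.5)
        g = np.repeat(["Z1", "Z2", "Z3"], 12)
        ours = tukey_hsd(y, g)
        sm = pairwise_tukeyhsd(y, g)
        np.testing.assert_allclose(ours["estimate"], sm.meandiffs, rtol=1e-10)
        np.testing.assert_allclose(ours["ci_low"], sm.confint[:, 0], rtol=1e-3)
        np.testing.assert_allclose(ours["ci_high"], sm.confint[:, 1], rtol=1e-3)
        np.testing.assert_allclose(ours["p_adjusted"], sm.pvalues, atol=2e-3)

    def test_ci_contains_estimate_and_widens(self):
        rng = np.random.default_rng(12)
        design = random_design(rng)
        res95 = tukey_from_design(design, conf_level=0.95)
        res99 = tukey_from_design(design, conf_level=0.99)
        assert ((res95["ci_low"] <= res95["estimate"]) & (res95["estimate"] <= res95["ci_high"])).all()
        assert (res99["ci_high"] - res99["ci_low"] > res95["ci_high"] - res95["ci_low"]).all()

    def test_design_tukey_uses_model_residual(self):
        rng = np.random.default_rng(13)
        design = random_design(rng)
        res = anova_type2(design)
        ours = tukey_from_design(design)
        manual = tukey_hsd(
            design["mean_retention"],
            design["GOf"],
            ms_resid=res.table.loc["Residual", "mean_sq"],
            df_resid=res.residual_df,
        )
        pd.testing.assert_frame_equal(ours, manual)

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            tukey_hsd([1.0, 2.0], ["a", "a"])
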