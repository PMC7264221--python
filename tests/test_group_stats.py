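import numpy as np
import pandas as pd
import pytest

from calrecruit import (
    ContingencyTable2x2,
    INTERACTION,
    bonferroni_posthoc,
    pearson_chi2_2x2,
    proportion_from_counts,
    two_way_anova,
)
from calrecruit.errors import (
    DegenerateTableError,
    DesignError,
    ParameterError,
    ReferenceError_,
)


def balanced_anova_oracle(cells):
    """Direct sums-of-squares two-way ANOVA for balanced designs.

    ``cells`` maps (a_level, b_level) -> list of observations, all the same
    length. Uses nothing but the textbook summation formulas, so it is an
    independent check on the model-based implementation.
    """
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    n = len(next(iter(cells.values())))
    all_vals = np.concatenate([np.asarray(v, float) for v in cells.values()])
    grand = all_vals.mean()
    cell_mean = {k: np.mean(v) for k, v in cells.items()}
    a_mean = {a: np.mean([cell_mean[(a, b)] for b in b_levels]) for a in a_levels}
    b_mean = {b: np.mean([cell_mean[(a, b)] for a in a_levels]) for b in b_levels}
    ss_a = n * len(b_levels) * sum((a_mean[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((b_mean[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (cell_mean[(a, b)] - a_mean[a] - b_mean[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_within = sum(
        float(np.sum((np.asarray(v, float) - cell_mean[k]) ** 2)) for k, v in cells.items()
    )
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_w = len(all_vals) - len(a_levels) * len(b_levels)
    ms_w = ss_within / df_w
    out = {
        "A": (ss_a / df_a) / ms_w if ms_w > 0 else 0.0,
        "B": (ss_b / df_b) / ms_w if ms_w > 0 else 0.0,
        "AB": (ss_ab / df_ab) / ms_w if ms_w > 0 else 0.0,
    }
    return out, (ss_a, ss_b, ss_ab, ss_within, float(np.sum((all_vals - grand) ** 2)))


def cells_to_frame(cells):
    rows = [
        {"y": val, "a": a, "b": b}
        for (a, b), vals in cells.items()
        for val in vals
    ]
    return pd.DataFrame(rows)


WORKED_CELLS = {
    ("a1", "b1"): [1, 2],
    ("a1", "b2"): [3, 4],
    ("a2", "b1"): [5, 6],
    ("a2", "b2"): [7, 8],
}


class TestTwoWayAnova:
    def test_worked_balanced_example_matches_oracle(self):
        oracle, _ = balanced_anova_oracle(WORKED_CELLS)
        assert oracle == {"A": 64.0, "B": 16.0, "AB": 0.0}
        result = two_way_anova(cells_to_frame(WORKED_CELLS), "y", "a", "b")
        assert result.effect("a").F == pytest.approx(64.0, rel=1e-10)
        assert result.effect("b").F == pytest.approx(16.0, rel=1e-10)
        assert result.effect(INTERACTION).F == pytest.approx(0.0, abs=1e-10)
        assert result.effect("a").df_num == 1 and result.effect("a").df_den == 4

    def test_constant_response_gives_zero_f(self):
        cells = {k: [2.0, 2.0] for k in WORKED_CELLS}
        result = two_way_anova(cells_to_frame(cells), "y", "a", "b")
        assert all(e.F == 0.0 and e.p == 1.0 for e in result.effects.values())

    def test_empty_cell_rejected_with_cell_named(self):
        df = cells_to_frame(WORKED_CELLS)
        df = df[~((df.a == "a2") & (df.b == "b2"))]
        with pytest.raises(DesignError, match="a2"):
            two_way_anova(df, "y", "a", "b")

    def test_single_level_factor_rejected(self):
        df = cells_to_frame(WORKED_CELLS)
        with pytest.raises(DesignError):
            two_way_anova(df[df.a == "a1"], "y", "a", "b")

    @pytest.mark.parametrize("shape,n", [((2, 2), 3), ((2, 3), 4), ((3, 3), 5)])
    def test_random_balanced_designs_agree_with_oracle(self, shape, n):
        rng = np.random.default_rng(shape[0] * 10 + shape[1] + n)
        for _ in range(8):
            cells = {
                (f"a{i}", f"b{j}"): rng.normal(rng.normal(0, 2), 1, n).tolist()
                for i in range(shape[0])
                for j in range(shape[1])
            }
            oracle, ss = balanced_anova_oracle(cells)
            result = two_way_anova(cells_to_frame(cells), "y", "a", "b")
            assert result.effect("a").F == pytest.approx(oracle["A"], rel=1e-8)
            assert result.effect("b").F == pytest.approx(oracle["B"], rel=1e-8)
            assert result.effect(INTERACTION).F == pytest.approx(oracle["AB"], rel=1e-8)
            # decomposition: SS_A + SS_B + SS_AB + SS_within = SS_total
            ss_a, ss_b, ss_ab, ss_w, ss_tot = ss
            assert ss_a + ss_b + ss_ab + ss_w == pytest.approx(ss_tot, rel=1e-8)

    def test_null_interaction_rejection_rate_near_alpha(self):
        # Gaussian null, balanced 2x2 with n = 5: the interaction F test is
        # exact, so the rejection rate at alpha = 0.05 must be ~5%
        rng = np.random.default_rng(99)
        hits = 0
        reps = 400
        for _ in range(reps):
            cells = {k: rng.normal(0, 1, 5).tolist() for k in WORKED_CELLS}
            result = two_way_anova(cells_to_frame(cells), "y", "a", "b")
            hits += result.effect(INTERACTION).p < 0.05
        assert abs(hits / reps - 0.05) < 0.025

    def test_unbalanced_design_accepted(self):
        cells = dict(WORKED_CELLS)
        cells[("a1", "b1")] = [1, 2, 3, 1.5]
        result = two_way_anova(cells_to_frame(cells), "y", "a", "b")
        assert result.effect("a").F > 0


class TestBonferroni:
    def test_single_comparison_equals_raw_p(self):
        df = cells_to_frame(WORKED_CELLS)
        out = bonferroni_posthoc(df, "y", "a", "b", [(("a1", "b1"), ("a2", "b1"))])
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_identical_groups_adjust_to_one(self):
        cells = {k: [1.0, 2.0] for k in WORKED_CELLS}
        df = cells_to_frame(cells)
        comps = [(("a1", "b1"), ("a1", "b2")), (("a2", "b1"), ("a2", "b2"))]
        out = bonferroni_posthoc(df, "y", "a", "b", comps)
        assert (out["p_adjusted"] == 1.0).all()

    def test_adjusted_p_monotone_in_comparison_count(self):
        df = cells_to_frame(WORKED_CELLS)
        comp = (("a1", "b1"), ("a2", "b2"))
        single = bonferroni_posthoc(df, "y", "a", "b", [comp])
        triple = bonferroni_posthoc(df, "y", "a", "b", [comp] * 3)
        assert triple["p_adjusted"].iloc[0] >= single["p_adjusted"].iloc[0]
        assert (triple["p_adjusted"] >= triple["p_raw"]).all()

    def test_unknown_cell_rejected(self):
        df = cells_to_frame(WORKED_CELLS)
        with pytest.raises(ReferenceError_):
            bonferroni_posthoc(df, "y", "a", "b", [(("a1", "b1"), ("zz", "b1"))])

    def test_shifted_cell_detected_in_most_replicates(self):
        # one cell shifted by 2 SD, n = 10 per cell, 4 comparisons:
        # its adjusted p must fall below 0.05 in >= 80% of seeded replicates
        hits = 0
        reps = 50
        comps = [
            (("a1", "b1"), ("a1", "b2")),
            (("a1", "b1"), ("a2", "b1")),
            (("a2", "b2"), ("a1", "b2")),
            (("a2", "b2"), ("a2", "b1")),
        ]
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            cells = {k: rng.normal(0, 1, 10).tolist() for k in WORKED_CELLS}
            cells[("a1", "b1")] = rng.normal(2.0, 1, 10).tolist()
            out = bonferroni_posthoc(cells_to_frame(cells), "y", "a", "b", comps)
            hits += out["p_adjusted"].iloc[0] < 0.05
        assert hits / reps >= 0.8


class TestProportions:
    @pytest.mark.parametrize(
        "events,total,expected", [(8, 18, 44.4), (8, 21, 38.1), (0, 7, 0.0), (7, 7, 100.0)]
    )
    def test_percentages_to_one_decimal(self, events, total, expected):
        assert proportion_from_counts(events, total) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            proportion_from_counts(1, 0)
        with pytest.raises(ParameterError):
            proportion_from_counts(5, 3)


class TestChi2:
    def test_perfect_independence_gives_zero(self):
        stat, df, p = pearson_chi2_2x2(np.array([[5, 5], [5, 5]]))
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_seizure_incidence_counts_match_direct_formula(self):
        # 8/18 vs 8/21 as a 2x2 table (events vs non-events per group)
        table = np.array([[8, 10], [8, 13]])
        stat, df, p = pearson_chi2_2x2(table)
        # independent check with the closed-form N(ad - bc)^2 / products
        n = table.sum()
        a, b = table[0]
        c, d = table[1]
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert stat == pytest.approx(closed, rel=1e-12)
        assert stat == pytest.approx(0.1615, abs=5e-4)

    def test_agrees_with_scipy_with_and_without_yates(self):
        from scipy.stats import chi2_contingency

        table = np.array([[8, 10], [8, 13]])
        for yates in (False, True):
            stat, df, p = pearson_chi2_2x2(table, yates=yates)
            ref = chi2_contingency(table, correction=yates)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_doubling_counts_doubles_uncorrected_statistic(self):
        table = np.array([[8, 10], [8, 13]])
        s1, _, _ = pearson_chi2_2x2(table)
        s2, _, _ = pearson_chi2_2x2(2 * table)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2_2x2(np.array([[0, 0], [5, 5]]))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ParameterError):
            ContingencyTable2x2(np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(ParameterError):
            ContingencyTable2x2(np.array([[-1, 2], [3, 4]]))
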