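"""Inference tests: contrasts, mixed RM-ANOVA vs independent oracles, trends.

Oracle strategy: small crossed designs are checked against (a) textbook
cell-mean formulas implemented inline, (b) pingouin, (c) statsmodels AnovaRM,
and (d) frozen reference values from an independent Type III mixed-model
implementation for the unbalanced between-groups case.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from fittslab import (
    bonferroni,
    format_anova,
    mauchly_test,
    poly_contrast_weights,
    rm_anova,
    trend_test,
)
from fittslab.inferential import _orthonormal_contrasts


def long_format(Y, factors):
    """Wide (subjects x cells) -> long DataFrame; cells row-major over
    ``factors`` = {name: levels}."""
    names = list(factors)
    grids = [list(factors[n]) for n in names]
    rows = []
    for i, row in enumerate(np.atleast_2d(Y)):
        idx = pd.MultiIndex.from_product(grids, names=names)
        for cell, y in zip(idx, row):
            rows.append({"subject": f"S{i:02d}", "y": float(y),
                         **dict(zip(names, cell))})
    return pd.DataFrame(rows)


def normalize(df):
    out = df.copy()
    out.columns = [str(c).replace("-", "_") for c in out.columns]
    return out


# ---------------------------------------------------------------------------
# Orthogonal polynomial contrasts


class TestPolyContrasts:
    def test_equally_spaced_reduce_to_integer_patterns(self):
        w = poly_contrast_weights([1.0, 2.0, 3.0, 4.0])
        expected = np.array([[-3.0, -1.0, 1.0, 3.0],
                             [1.0, -1.0, -1.0, 1.0],
                             [-1.0, 3.0, -3.0, 1.0]])
        expected /= np.linalg.norm(expected, axis=1, keepdims=True)
        assert np.allclose(w, expected, atol=1e-12)

    def test_unequal_spacing_stays_orthonormal(self):
        w = poly_contrast_weights([155.0, 190.0, 266.0, 380.0])
        assert np.allclose(w @ w.T, np.eye(3), atol=1e-12)
        assert np.allclose(w.sum(axis=1), 0.0, atol=1e-12)
        # the linear contrast increases along the levels
        assert np.all(np.diff(w[0]) > 0)

    @given(st.lists(st.floats(-100.0, 100.0), min_size=3, max_size=6,
                    unique=True))
    def test_rows_always_sum_zero_and_orthonormal(self, levels):
        w = poly_contrast_weights(sorted(levels))
        k = len(levels)
        assert np.allclose(w @ w.T, np.eye(k - 1), atol=1e-8)
        assert np.allclose(w.sum(axis=1), 0.0, atol=1e-8)

    def test_rejects_bad_levels(self):
        with pytest.raises(ValueError):
            poly_contrast_weights([1.0])
        with pytest.raises(ValueError):
            poly_contrast_weights([1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            poly_contrast_weights([1.0, 2.0, 3.0], max_order=3)


# ---------------------------------------------------------------------------
# RM-ANOVA vs textbook cell-mean formulas (self-contained oracle)


class TestTextbookFormulas:
    def test_one_way_within(self):
        rng = np.random.default_rng(101)
        n, k = 8, 4
        Y = rng.normal(300.0, 40.0, size=(n, k)) + \
            np.linspace(0.0, 60.0, k)
        table = rm_anova(long_format(Y, {"a": range(k)}), "y", "a", "subject")
        grand = Y.mean()
        ss_a = n * np.sum((Y.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
        ss_total = np.sum((Y - grand) ** 2)
        ss_err = ss_total - ss_a - ss_subj
        f_ref = (ss_a / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        row = table.iloc[0]
        assert row["ss_effect"] == pytest.approx(ss_a, rel=1e-10)
        assert row["ss_error"] == pytest.approx(ss_err, rel=1e-10)
        assert row["F"] == pytest.approx(f_ref, rel=1e-10)
        assert row["p"] == pytest.approx(
            stats.f.sf(f_ref, k - 1, (n - 1) * (k - 1)), rel=1e-10)
        assert table.attrs["ss_subjects"] == pytest.approx(ss_subj, rel=1e-10)
        assert table.attrs["ss_total"] == pytest.approx(ss_total, rel=1e-10)

    def test_two_way_within(self):
        rng = np.random.default_rng(202)
        n, ka, kb = 6, 3, 4
        Y = rng.normal(0.0, 1.0, size=(n, ka * kb))
        table = rm_anova(long_format(Y, {"a": range(ka), "b": range(kb)}),
                         "y", ["a", "b"], "subject")
        M = Y.reshape(n, ka, kb)
        g = M.mean()
        m_i, m_a, m_b = M.mean((1, 2)), M.mean((0, 2)), M.mean((0, 1))
        m_ia, m_ib, m_ab = M.mean(2), M.mean(1), M.mean(0)
        ss = {
            "a": n * kb * np.sum((m_a - g) ** 2),
            "b": n * ka * np.sum((m_b - g) ** 2),
            "a:b": n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2),
        }
        err = {
            "a": kb * np.sum((m_ia - m_i[:, None] - m_a[None, :] + g) ** 2),
            "b": ka * np.sum((m_ib - m_i[:, None] - m_b[None, :] + g) ** 2),
        }
        err["a:b"] = (np.sum((M - g) ** 2)
                      - ka * kb * np.sum((m_i - g) ** 2)
                      - sum(ss.values()) - err["a"] - err["b"])
        dfs = {"a": ka - 1, "b": kb - 1, "a:b": (ka - 1) * (kb - 1)}
        for effect, dfn in dfs.items():
            row = table.set_index("effect").loc[effect]
            dfd = dfn * (n - 1)
            f_ref = (ss[effect] / dfn) / (err[effect] / dfd)
            assert row["ss_effect"] == pytest.approx(ss[effect], abs=1e-10)
            assert row["ss_error"] == pytest.approx(err[effect], abs=1e-10)
            assert row["F"] == pytest.approx(f_ref, rel=1e-9)
            assert row["df_num"] == dfn and row["df_den"] == dfd


# ---------------------------------------------------------------------------
# RM-ANOVA vs library oracles


class TestLibraryOracles:
    def test_one_way_matches_pingouin(self):
        rng = np.random.default_rng(303)
        n, k = 8, 4
        Y = rng.normal(400.0, 60.0, size=(n, k)) + np.linspace(0, 80, k)
        data = long_format(Y, {"a": range(k)})
        mine = rm_anova(data, "y", "a", "subject").iloc[0]
        ref = normalize(pg.rm_anova(data=data, dv="y", within="a",
                                    subject="subject", detailed=True,
                                    effsize="ng2")).iloc[0]
        assert mine["F"] == pytest.approx(ref["F"], rel=1e-9)
        assert mine["p"] == pytest.approx(ref["p_unc"], rel=1e-9)
        assert mine["eta_sq_gen"] == pytest.approx(ref["ng2"], rel=1e-9)
        assert mine["gg_epsilon"] == pytest.approx(ref["eps"], rel=1e-9)
        sph = pg.sphericity(data=data, dv="y", within="a", subject="subject")
        assert mine["mauchly_w"] == pytest.approx(sph.W, rel=1e-9)
        assert mine["mauchly_p"] == pytest.approx(sph.pval, rel=1e-9)

    def test_two_way_matches_pingouin(self):
        rng = np.random.default_rng(404)
        n, ka, kb = 10, 2, 3
        Y = rng.normal(0.0, 1.0, size=(n, ka * kb))
        Y[:, :kb] += 0.8      # main effect of the first factor
        data = long_format(Y, {"a": range(ka), "b": range(kb)})
        mine = rm_anova(data, "y", ["a", "b"], "subject").set_index("effect")
        ref = normalize(pg.rm_anova(data=data, dv="y", within=["a", "b"],
                                    subject="subject", effsize="ng2"))
        ref = ref.set_index("Source")
        for theirs, ours in (("a", "a"), ("b", "b"), ("a * b", "a:b")):
            assert mine.loc[ours, "F"] == \
                pytest.approx(ref.loc[theirs, "F"], rel=1e-9)
            assert mine.loc[ours, "p"] == \
                pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-9)
            assert mine.loc[ours, "eta_sq_gen"] == \
                pytest.approx(ref.loc[theirs, "ng2"], rel=1e-9)

    def test_three_way_matches_statsmodels(self):
        rng = np.random.default_rng(505)
        n = 6
        Y = rng.normal(0.0, 1.0, size=(n, 2 * 3 * 2))
        data = long_format(Y, {"a": range(2), "b": range(3), "c": range(2)})
        mine = rm_anova(data, "y", ["a", "b", "c"],
                        "subject").set_index("effect")
        ref = AnovaRM(data, "y", "subject",
                      within=["a", "b", "c"]).fit().anova_table
        for effect in ref.index:
            assert mine.loc[effect, "F"] == \
                pytest.approx(ref.loc[effect, "F Value"], rel=1e-9)
            assert mine.loc[effect, "p"] == \
                pytest.approx(ref.loc[effect, "Pr > F"], rel=1e-9)
            assert mine.loc[effect, "df_num"] == ref.loc[effect, "Num DF"]
            assert mine.loc[effect, "df_den"] == ref.loc[effect, "Den DF"]


class TestUnbalancedMixedFrozenOracle:
    """Type III mixed design, groups of 4 and 2 subjects, 3 within levels.

    Reference values computed once with an independent Type III mixed-model
    ANOVA implementation on this exact integer dataset.
    """

    Y = np.array([[10.0, 12.0, 15.0],
                  [11.0, 14.0, 18.0],
                  [9.0, 11.0, 12.0],
                  [12.0, 15.0, 19.0],
                  [20.0, 19.0, 23.0],
                  [18.0, 21.0, 26.0]])
    GROUPS = ["A", "A", "A", "A", "B", "B"]

    def table(self):
        data = long_format(self.Y, {"w": ["w1", "w2", "w3"]})
        data["g"] = np.repeat(self.GROUPS, 3)
        return rm_anova(data, "y", "w", "subject", between="g").set_index(
            "effect")

    def test_type3_sums_of_squares_and_f(self):
        t = self.table()
        expected = {
            "g": (256.0, 40.5, 25.2839506173, 0.00734219960315),
            "w": (84.2222222222, 13.0, 25.9145299145, 0.000319676885138),
            "g:w": (2.0, 13.0, 0.615384615385, 0.564167901235),
        }
        for effect, (ss, ss_err, f, p) in expected.items():
            assert t.loc[effect, "ss_effect"] == pytest.approx(ss, rel=1e-9)
            assert t.loc[effect, "ss_error"] == pytest.approx(ss_err, rel=1e-9)
            assert t.loc[effect, "F"] == pytest.approx(f, rel=1e-9)
            assert t.loc[effect, "p"] == pytest.approx(p, rel=1e-9)

    def test_greenhouse_geisser_from_pooled_within_group_covariance(self):
        t = self.table()
        for effect in ("w", "g:w"):
            assert t.loc[effect, "gg_epsilon"] == \
                pytest.approx(0.600710900474, rel=1e-9)
        assert t.loc["w", "p_gg"] == pytest.approx(0.00373189701839, rel=1e-9)
        assert t.loc["g:w", "p_gg"] == pytest.approx(0.499259821027, rel=1e-9)

    def test_mauchly_statistic(self):
        t = self.table()
        assert t.loc["w", "mauchly_w"] == \
            pytest.approx(0.335305719921, rel=1e-9)
        assert t.loc["w", "mauchly_p"] == \
            pytest.approx(0.194160750964, rel=1e-9)


# ---------------------------------------------------------------------------
# Sphericity machinery


class TestSphericity:
    def test_whitened_scores_give_epsilon_one_and_mauchly_one(self):
        # rebuild cell data whose contrast scores have exactly spherical
        # covariance: epsilon must hit its upper bound and Mauchly W = 1
        rng = np.random.default_rng(606)
        n, k = 12, 4
        Y = rng.normal(0.0, 1.0, size=(n, k))
        M = _orthonormal_contrasts(k)
        u = np.full(k, 1.0 / np.sqrt(k))
        Z = Y @ M
        Zc = Z - Z.mean(axis=0)
        chol = np.linalg.cholesky(Zc.T @ Zc / (n - 1))
        Zw = Z.mean(axis=0) + Zc @ np.linalg.inv(chol).T
        Yw = np.outer(Y @ u, u) + Zw @ M.T
        table = rm_anova(long_format(Yw, {"a": range(k)}), "y", "a", "subject")
        row = table.iloc[0]
        assert row["gg_epsilon"] == pytest.approx(1.0, abs=1e-10)
        assert row["mauchly_w"] == pytest.approx(1.0, abs=1e-10)
        assert row["mauchly_p"] == pytest.approx(1.0, abs=1e-8)
        assert row["p_gg"] == pytest.approx(row["p"], rel=1e-10)

    def test_two_level_factor_has_no_sphericity_question(self):
        rng = np.random.default_rng(707)
        Y = rng.normal(0.0, 1.0, size=(6, 2))
        row = rm_anova(long_format(Y, {"a": range(2)}), "y", "a",
                       "subject").iloc[0]
        assert row["gg_epsilon"] == 1.0
        assert np.isnan(row["mauchly_w"])
        assert np.isnan(row["mauchly_p"])
        # an uncomputable test defaults to the (identical) corrected p
        assert row["sphericity_violated"]
        assert row["p_headline"] == row["p_gg"] == row["p"]

    def test_mauchly_undefined_for_single_contrast_dimension(self):
        assert np.isnan(mauchly_test(np.array([[2.0]]), 10)[0])
        # too few error degrees of freedom to estimate the covariance
        assert np.isnan(mauchly_test(np.eye(3), 3)[0])


# ---------------------------------------------------------------------------
# Edge cases and validation


class TestValidation:
    def test_zero_variance_error_term_gives_nan_f(self):
        Y = np.tile([1.0, 2.0, 3.0], (4, 1))   # identical subjects
        table = rm_anova(long_format(Y, {"a": range(3)}), "y", "a", "subject")
        assert np.isnan(table.iloc[0]["F"])
        report = format_anova(table)
        assert "not applicable" in report

    def test_subject_in_two_groups_rejected(self):
        data = long_format(np.zeros((4, 2)), {"a": range(2)})
        # first subject's two rows land in different groups
        data["g"] = ["x", "y"] + ["x", "x"] + ["y", "y"] + ["y", "y"]
        with pytest.raises(ValueError, match="more than one group"):
            rm_anova(data, "y", "a", "subject", between="g")

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(1)
        data = long_format(rng.normal(size=(3, 2)), {"a": range(2)})
        data["g"] = ["x", "x", "x", "x", "y", "y"]
        with pytest.raises(ValueError, match=">= 2 subjects"):
            rm_anova(data, "y", "a", "subject", between="g")

    def test_incomplete_subject_excluded(self):
        rng = np.random.default_rng(2)
        data = long_format(rng.normal(size=(5, 3)), {"a": range(3)})
        data = data.drop(data.index[-1])     # last subject loses one cell
        table = rm_anova(data, "y", "a", "subject")
        assert table.attrs["n_subjects"] == 4

    def test_requires_within_factor_and_two_subjects(self):
        data = long_format(np.zeros((1, 3)), {"a": range(3)})
        with pytest.raises(ValueError):
            rm_anova(data, "y", [], "subject")
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova(data, "y", "a", "subject")


# ---------------------------------------------------------------------------
# Trend tests and multiplicity


class TestTrendTest:
    def test_manual_formula(self):
        scores_means = np.array([[1.0, 2.0, 4.0],
                                 [0.0, 2.0, 5.0],
                                 [1.0, 3.0, 4.0],
                                 [2.0, 2.0, 6.0]])
        w = poly_contrast_weights([1.0, 2.0, 3.0])[0]
        res = trend_test(scores_means, w, factor="a", order=1)
        scores = scores_means @ w
        ss_num = len(scores) * scores.mean() ** 2
        ss_err = np.sum((scores - scores.mean()) ** 2)
        f_ref = ss_num / (ss_err / (len(scores) - 1))
        assert res.F == pytest.approx(f_ref, rel=1e-12)
        assert res.p == pytest.approx(stats.f.sf(f_ref, 1, 3), rel=1e-12)
        assert res.order == "linear"
        assert res.df_den == 3

    def test_detects_planted_linear_trend(self):
        rng = np.random.default_rng(808)
        levels = np.array([155.0, 190.0, 266.0, 380.0])
        Y = 2.0 * np.log2(levels) + rng.normal(0, 0.05, size=(10, 4))
        w_lin, w_quad = poly_contrast_weights(np.log2(levels))[:2]
        lin = trend_test(Y, w_lin, order=1)
        quad = trend_test(Y, w_quad, order=2)
        assert lin.p < 1e-6
        assert quad.p > 0.01

    def test_degenerate_scores(self):
        res = trend_test(np.ones((4, 3)), poly_contrast_weights([1., 2., 3.])[0])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            trend_test(np.ones((4, 3)), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            trend_test(np.ones((1, 3)), np.array([1.0, 0.0, -1.0]))


class TestBonferroni:
    def test_scalar_and_array(self):
        assert bonferroni(0.01, m=3) == pytest.approx(0.03)
        assert np.allclose(bonferroni([0.01, 0.5]), [0.02, 1.0])

    def test_caps_at_one(self):
        assert bonferroni(0.9, m=5) == 1.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_adjusted_never_smaller(self, ps):
        adj = np.atleast_1d(bonferroni(ps))
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni([-0.1])
        with pytest.raises(ValueError):
            bonferroni([0.5], m=0)
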