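import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from bodyrsa.groupstats import (
    chi_square_2x2,
    framewise_displacement,
    mixed_anova,
    partial_correlation,
    posthoc_pairwise,
    spearman_with_bonferroni,
    two_sample_t,
    two_sample_t_from_stats,
)


class TestChiSquare:
    def test_left_hemisphere_activation_table(self):
        # 26/26 adults vs 17/22 children activated
        res = chi_square_2x2([[26, 0], [17, 5]])
        assert res.statistic == pytest.approx(6.596, abs=5e-4)
        assert res.cramers_v == pytest.approx(0.37, abs=5e-3)
        assert res.p == pytest.approx(0.010, abs=5e-4)

    def test_right_hemisphere_activation_table(self):
        res = chi_square_2x2([[26, 0], [21, 1]])
        assert res.statistic == pytest.approx(1.207, abs=5e-4)
        assert res.cramers_v == pytest.approx(0.16, abs=5e-3)

    def test_independent_rows_give_zero(self):
        res = chi_square_2x2([[10, 5], [10, 5]])
        assert res.statistic == 0.0
        assert res.cramers_v == 0.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[5, 0], [7, 0]])

    def test_matches_scipy_over_small_count_grid(self):
        for a, b, c, d in itertools.product(range(1, 5), repeat=4):
            res = chi_square_2x2([[a, b], [c, d]])
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_continuity_correction_matches_scipy(self):
        res = chi_square_2x2([[26, 0], [17, 5]], continuity_correction=True)
        ref = chi2_contingency([[26, 0], [17, 5]], correction=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)


class TestTwoSampleT:
    def test_fd_summary_welch_df(self):
        # printed FD summaries: 0.19 +/- 0.14 (n=22) vs 0.10 +/- 0.06 (n=26)
        res = two_sample_t_from_stats(0.19, 0.14, 22, 0.10, 0.06, 26, mode="welch")
        assert round(res.df, 1) == 27.5
        # t from the rounded summaries (the unrounded data are not
        # available, so only df is checked at printed precision)
        assert res.t == pytest.approx(2.81, abs=0.01)
        assert res.p < 0.01

    def test_identical_samples(self):
        x = np.arange(10.0)
        res = two_sample_t(x, x, mode="student")
        assert res.t == 0.0
        assert res.cohens_d == 0.0
        assert res.p == pytest.approx(1.0)

    def test_student_df(self):
        res = two_sample_t(np.random.default_rng(0).normal(size=10),
                           np.random.default_rng(1).normal(size=10),
                           mode="student")
        assert res.df == 18

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 2, 20)
        for mode, equal_var in (("student", True), ("welch", False)):
            res = two_sample_t(x, y, mode=mode)
            ref = stats.ttest_ind(x, y, equal_var=equal_var)
            assert res.t == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(1, 2, size=12)
        a = two_sample_t(x, y)
        b = two_sample_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.cohens_d == pytest.approx(-b.cohens_d)
        assert a.df == pytest.approx(b.df)


def brute_force_mixed_ss(Y, groups):
    """Direct sums-of-squares decomposition by explicit cell loops."""
    n, k = Y.shape
    gm = Y.mean()
    gnames = sorted(set(groups))
    ss = {"group": 0.0, "subj": 0.0, "within": 0.0, "inter": 0.0}
    for gn in gnames:
        sub = Y[[i for i, g in enumerate(groups) if g == gn]]
        ss["group"] += k * len(sub) * (sub.mean() - gm) ** 2
        for row in sub:
            ss["subj"] += k * (row.mean() - sub.mean()) ** 2
    for j in range(k):
        ss["within"] += n * (Y[:, j].mean() - gm) ** 2
    for gn in gnames:
        idx = [i for i, g in enumerate(groups) if g == gn]
        sub = Y[idx]
        for j in range(k):
            ss["inter"] += len(idx) * (
                sub[:, j].mean() - sub.mean() - Y[:, j].mean() + gm
            ) ** 2
    ss["err_w"] = ((Y - gm) ** 2).sum() - sum(
        ss[x] for x in ("group", "subj", "within", "inter")
    )
    return ss


def _long(Y, groups):
    rows = []
    for i, (row, g) in enumerate(zip(Y, groups)):
        for j, v in enumerate(row):
            rows.append({"id": f"s{i}", "group": g, "level": f"l{j}", "y": v})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_brute_force_oracle_on_toy(self):
        Y = np.array([[1.0, 3.0], [2.0, 5.0], [4.0, 4.0], [6.0, 9.0]])
        groups = ["a", "a", "b", "b"]
        res = mixed_anova(_long(Y, groups), dv="y", within="level",
                          between="group", subject="id")
        ss = brute_force_mixed_ss(Y, groups)
        f_group = (ss["group"] / 1) / (ss["subj"] / 2)
        f_within = (ss["within"] / 1) / (ss["err_w"] / 2)
        f_inter = (ss["inter"] / 1) / (ss["err_w"] / 2)
        assert res.effect("group")["F"] == pytest.approx(f_group)
        assert res.effect("within")["F"] == pytest.approx(f_within)
        assert res.effect("interaction")["F"] == pytest.approx(f_inter)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(12, 4)) + np.array([0, 0.5, 1, 0])[None, :]
        groups = ["a"] * 6 + ["b"] * 6
        df = _long(Y, groups)
        res = mixed_anova(df, dv="y", within="level", between="group", subject="id")
        ref = pg.mixed_anova(df, dv="y", within="level", between="group",
                             subject="id")
        ref = ref.set_index("Source")
        assert res.effect("group")["F"] == pytest.approx(ref.loc["group", "F"])
        assert res.effect("within")["F"] == pytest.approx(ref.loc["level", "F"])
        assert res.effect("interaction")["F"] == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        assert res.effect("within")["partial_eta_sq"] == pytest.approx(
            ref.loc["level", "np2"]
        )

    def test_identical_groups_give_zero_group_f(self):
        Y = np.tile(np.array([[1.0, 2.0, 3.0]]), (6, 1))
        Y += np.arange(6)[:, None] % 3 * 0.5  # same pattern in both groups
        groups = ["a", "b"] * 3
        res = mixed_anova(_long(Y, groups), dv="y", within="level",
                          between="group", subject="id")
        assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-10)

    def test_total_ss_conservation(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(10, 5))
        groups = ["a"] * 5 + ["b"] * 5
        res = mixed_anova(_long(Y, groups), dv="y", within="level",
                          between="group", subject="id")
        ss = brute_force_mixed_ss(Y, groups)
        total = ((Y - Y.mean()) ** 2).sum()
        assert sum(ss.values()) == pytest.approx(total)

    def test_partial_eta_sq_bounded(self):
        for s in range(30):
            rng = np.random.default_rng(s)
            Y = rng.normal(size=(8, 3))
            groups = ["a"] * 4 + ["b"] * 4
            res = mixed_anova(_long(Y, groups), dv="y", within="level",
                              between="group", subject="id")
            assert ((res.effects.partial_eta_sq >= 0)
                    & (res.effects.partial_eta_sq <= 1)).all()

    def test_covariate_reduces_confounded_group_effect(self):
        # group difference fully explained by the covariate
        rng = np.random.default_rng(5)
        cov = np.r_[np.zeros(10), np.ones(10)] * 2.0
        Y = rng.normal(size=(20, 2)) * 0.1 + cov[:, None]
        groups = ["a"] * 10 + ["b"] * 10
        df = _long(Y, groups)
        df["fd"] = np.repeat(cov + rng.normal(0, 0.01, 20), 2)
        plain = mixed_anova(df, dv="y", within="level", between="group",
                            subject="id")
        adj = mixed_anova(df, dv="y", within="level", between="group",
                          subject="id", covariate="fd")
        assert adj.effect("group")["F"] < plain.effect("group")["F"]
        assert adj.effect("group")["df2"] == plain.effect("group")["df2"] - 1

    def test_missing_cells_rejected(self):
        df = _long(np.ones((4, 2)), ["a", "a", "b", "b"]).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(df, dv="y", within="level", between="group", subject="id")


class TestPosthoc:
    def test_28_comparisons_for_8_levels(self):
        rng = np.random.default_rng(6)
        df = _long(rng.normal(size=(6, 8)), ["a"] * 6)
        out = posthoc_pairwise(df, dv="y", within="level", subject="id")
        assert len(out) == 28
        assert np.allclose(
            out.p_corrected, np.minimum(1.0, 28 * out.p_uncorrected)
        )

    def test_identical_levels_give_p_one(self):
        df = _long(np.tile([[2.0, 2.0, 2.0]], (5, 1)), ["a"] * 5)
        out = posthoc_pairwise(df, dv="y", within="level", subject="id")
        assert (out.p_corrected == 1.0).all()


class TestSpearman:
    def test_bonferroni_threshold_for_10_scores(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(rng.normal(size=(20, 10)),
                              columns=[f"s{i}" for i in range(10)])
        rep = spearman_with_bonferroni(rng.normal(size=20), scores)
        assert rep.corrected_threshold == pytest.approx(0.005)
        assert len(rep.table) == 10

    def test_monotone_pair_gives_rho_one(self):
        x = np.arange(10.0)
        rep = spearman_with_bonferroni(x, pd.DataFrame({"s": np.exp(x)}))
        assert rep.table.rho[0] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        a = spearman_with_bonferroni(x, pd.DataFrame({"s": y})).table.rho[0]
        b = spearman_with_bonferroni(np.exp(x), pd.DataFrame({"s": y**3})).table.rho[0]
        assert a == pytest.approx(b)


class TestPartialCorrelation:
    def test_independent_covariate_leaves_r_unchanged(self):
        deltas = []
        for s in range(50):
            rng = np.random.default_rng(s)
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40)
            c = rng.normal(size=40)
            r, df, _ = partial_correlation(x, y, c)
            deltas.append(r - np.corrcoef(x, y)[0, 1])
            assert df == 37
        assert abs(np.mean(deltas)) < 0.02

    def test_covariate_driven_y_gives_zero_partial(self):
        rs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            c = rng.normal(size=40)
            y = c + rng.normal(0, 0.1, size=40)
            x = rng.normal(size=40)
            rs.append(partial_correlation(x, y, c)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.normal(size=25)})
        df["c"] = rng.normal(size=25) + 0.3 * df.x
        df["y"] = 0.4 * df.x + 0.5 * df.c + rng.normal(size=25)
        r, dof, p = partial_correlation(df.x, df.y, df.c)
        ref = pg.partial_corr(df, x="x", y="y", covar="c")
        assert r == pytest.approx(ref["r"].iloc[0], abs=1e-9)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(ref[pcol].iloc[0], abs=1e-9)

    def test_collinear_covariate_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, np.random.default_rng(0).normal(size=10), 2 * x)


class TestFramewiseDisplacement:
    def test_constant_trace_zero(self):
        assert framewise_displacement(np.ones((20, 6))).mean_fd == 0.0

    def test_single_translation_step(self):
        m = np.zeros((5, 6))
        m[3:, 0] = 1.0
        fd = framewise_displacement(m)
        assert fd.fd[3] == pytest.approx(1.0)
        assert fd.fd[[0, 1, 2, 4]].tolist() == [0, 0, 0, 0]

    def test_rotation_steps_on_50mm_sphere(self):
        m = np.zeros((3, 6))
        m[2, 3:] = 0.02
        fd = framewise_displacement(m)
        assert fd.fd[2] == pytest.approx(50 * 0.06)

    @given(st.floats(-5, 5), st.integers(0, 5))
    @settings(max_examples=20, deadline=None)
    def test_offset_invariance(self, offset, col):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(30, 6))
        shifted = m.copy()
        shifted[:, col] += offset
        a = framewise_displacement(m)
        b = framewise_displacement(shifted)
        assert np.allclose(a.fd, b.fd)

    def test_first_volume_zero(self):
        m = np.random.default_rng(11).normal(size=(10, 6))
        assert framewise_displacement(m).fd[0] == 0.0
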