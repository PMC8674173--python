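"""Every evaluation statistic against an independently coded
direct-formula oracle on small random inputs."""

import numpy as np
import pytest
from scipy import stats as sps

from reachdecomp import stats as st


# ---------------------------------------------------------------------------
# direct-formula oracles (kept deliberately naive)


def oracle_rmse(e, y):
    return np.sqrt(sum((a - b) ** 2 for a, b in zip(e, y)) / len(e))


def oracle_auc(scores, labels):
    """O(n^2) count of concordant pairs; ties count half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_icc31(x):
    n, k = x.shape
    gm = x.mean()
    ms_r = k * ((x.mean(axis=1) - gm) ** 2).sum() / (n - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + gm
    ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def oracle_welch_anova(groups):
    w = [len(g) / np.var(g, ddof=1) for g in groups]
    xbar = [np.mean(g) for g in groups]
    W = sum(w)
    grand = sum(wi * xi for wi, xi in zip(w, xbar)) / W
    k = len(groups)
    num = sum(wi * (xi - grand) ** 2 for wi, xi in zip(w, xbar)) / (k - 1)
    lam = sum(
        (1 - wi / W) ** 2 / (len(g) - 1) for wi, g in zip(w, groups)
    )
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = num / den
    df2 = (k**2 - 1) / (3 * lam)
    p = sps.f.sf(f, k - 1, df2)
    return f, p


def oracle_welch_t(a, b):
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * sps.t.sf(abs(t), df)


def oracle_games_howell(a, b):
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    se = np.sqrt(va + vb)
    t = (np.mean(a) - np.mean(b)) / se
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


# ---------------------------------------------------------------------------


class TestPointMetrics:
    def test_rmse_identical(self):
        assert st.rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_rmse_constant_offset(self):
        y = np.array([1.0, 5.0, 9.0])
        assert st.rmse(y + 3, y) == pytest.approx(3.0)

    def test_rmse_random_oracle(self, rng):
        e, y = rng.normal(0, 5, 40), rng.normal(0, 5, 40)
        assert st.rmse(e, y) == pytest.approx(oracle_rmse(e, y), abs=1e-12)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            st.rmse([1, 2], [1, 2, 3])

    def test_r_squared_is_squared_pearson(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r, _ = sps.pearsonr(x, y)
        assert st.r_squared(x, y) == pytest.approx(r**2, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        auc, ci = st.auc_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=200, seed=0)
        assert auc == 1.0

    def test_reversed_scores_complement(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        a, _ = st.auc_ci(scores, labels, n_boot=50, seed=0)
        b, _ = st.auc_ci(-scores, labels, n_boot=50, seed=0)
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        scores = np.round(rng.normal(0, 1, 50), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        auc, _ = st.auc_ci(scores, labels, n_boot=50, seed=0)
        assert auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            st.auc_ci([0.1, 0.9], [1, 1])

    def test_ci_brackets_point_and_shrinks_with_n(self, rng):
        def width(n, seed):
            scores = np.r_[rng.normal(0, 1, n // 2), rng.normal(1.2, 1, n // 2)]
            labels = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
            auc, (lo, hi) = st.auc_ci(scores, labels, n_boot=400, seed=seed)
            assert lo <= auc <= hi
            return hi - lo

        assert width(160, 1) < width(40, 2)


class TestICC:
    def test_identical_columns(self):
        x = np.tile(np.array([[1.0], [4.0], [9.0], [2.5]]), (1, 2))
        res = st.icc31(x)
        assert res["icc"] == pytest.approx(1.0)

    def test_toy_table_against_anova_oracle(self, rng):
        x = rng.normal(10, 3, (4, 2)) + rng.normal(0, 1, (4, 2))
        res = st.icc31(x)
        assert res["icc"] == pytest.approx(oracle_icc31(x), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(5, 2, (8, 2)) + np.arange(8)[:, None]
        long = (
            pd.DataFrame(x)
            .reset_index()
            .melt(id_vars="index", var_name="rater", value_name="rating")
        )
        ref = pg.intraclass_corr(
            data=long, targets="index", raters="rater", ratings="rating"
        ).set_index("Type").loc["ICC(C,1)"]
        res = st.icc31(x)
        assert res["icc"] == pytest.approx(float(ref["ICC"]), abs=1e-8)
        np.testing.assert_allclose(res["ci"], ref["CI95"], atol=2e-2)  # CI printed to 2 dp

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(5)
        res = st.icc31(rng.normal(0, 1, (50, 2)))
        assert -0.3 < res["icc"] < 0.3

    def test_incomplete_rows_dropped(self, rng):
        x = rng.normal(0, 1, (6, 2))
        x[2, 1] = np.nan
        with pytest.warns(UserWarning):
            st.icc31(x)


class TestGroupTests:
    def test_welch_anova_matches_oracle(self, rng):
        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 12), (0.5, 2, 18), (1.5, 0.5, 9)]]
        f, p = st.welch_anova(groups)
        f0, p0 = oracle_welch_anova(groups)
        assert f == pytest.approx(f0, abs=1e-8)
        assert p == pytest.approx(p0, abs=1e-8)

    def test_welch_anova_shifted_groups_significant(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        _, p = st.welch_anova([a, b])
        assert p < 1e-6

    def test_welch_t_matches_oracle(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 2, 20)
        t, p = st.welch_t(a, b)
        t0, p0 = oracle_welch_t(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_one_sample_t(self, rng):
        x = rng.normal(0.5, 1, 25)
        t, p = st.one_sample_t(x)
        t0, p0 = sps.ttest_1samp(x, 0.0)
        assert t == pytest.approx(float(t0), abs=1e-12)
        assert p == pytest.approx(float(p0), abs=1e-12)

    def test_one_sample_t_all_zero(self):
        t, p = st.one_sample_t(np.zeros(10))
        assert (t, p) == (0.0, 1.0)

    def test_games_howell_statistics_match_oracle(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0, 1.5, 12), rng.normal(2, 1, 18)]
        table = st.games_howell(groups, names=["g0", "g1", "g2"])
        for _, row in table.iterrows():
            a = groups[int(row["A"][1])]
            b = groups[int(row["B"][1])]
            t0, df0 = oracle_games_howell(a, b)
            assert abs(row["T"]) == pytest.approx(abs(t0), abs=1e-8)
            assert row["df"] == pytest.approx(df0, abs=1e-8)
            # p from the studentized-range distribution with q = t*sqrt(2)
            p0 = sps.studentized_range.sf(abs(t0) * np.sqrt(2), 3, df0)
            assert row["p"] == pytest.approx(p0, abs=1e-6)

    def test_games_howell_flags_only_shifted_pair(self, rng):
        base = rng.normal(0, 1, 25)
        groups = [base, rng.normal(0, 1, 25), rng.normal(4, 1, 25)]
        table = st.games_howell(groups, names=["a", "b", "c"])
        sig = {(r["A"], r["B"]): r["p"] < 0.05 for _, r in table.iterrows()}
        assert sig[("a", "b")] is False or sig[("a", "b")] == False  # noqa: E712
        assert sig[("a", "c")] and sig[("b", "c")]
        assert not sig[("a", "b")]

    def test_identical_groups_f_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        f, p = st.welch_anova([g, g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
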