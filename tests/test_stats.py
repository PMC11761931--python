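"""Statistical operations against direct-formula and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from broilerwalk.stats import (
    fisher_exact,
    fit_feature_model,
    kmeans_gait_clusters,
    one_way_anova,
    pearson_cor_ci,
    welch_t,
)

X10 = np.array([1.2, 3.4, 2.2, 5.6, 4.4, 6.1, 0.7, 3.3, 5.0, 2.8])
Y10 = np.array([2.0, 3.1, 2.9, 6.0, 3.9, 7.2, 1.1, 2.5, 4.8, 3.5])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, lo, hi, p = pearson_cor_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, *_ = pearson_cor_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        r, lo, hi, p = pearson_cor_ci(X10, Y10)
        n = len(X10)
        xc, yc = X10 - X10.mean(), Y10 - Y10.mean()
        r_direct = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * np.sqrt((n - 2) / (1 - r_direct**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-12)
        z = np.arctanh(r_direct)
        assert lo == pytest.approx(np.tanh(z - 1.959963984540054 / np.sqrt(n - 3)), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_cor_ci(np.ones(10), Y10)


class TestFisherExact:
    def test_two_by_two_diagonal(self):
        # both margin-consistent tables have probability 1/2
        assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[3, 5], [6, 2]],
        [[10, 2], [4, 9]],
        [[1, 7], [7, 1]],
        [[12, 5], [3, 8]],
    ])
    def test_matches_scipy_on_2x2(self, table):
        assert fisher_exact(table) == pytest.approx(
            sps.fisher_exact(table)[1], rel=1e-9)

    def test_permutation_invariance(self):
        t = np.array([[8, 3, 2], [1, 6, 4], [2, 2, 5]])
        p = fisher_exact(t)
        rng = np.random.default_rng(0)
        for _ in range(5):
            rp = rng.permutation(3)
            cp = rng.permutation(3)
            assert fisher_exact(t[rp][:, cp]) == pytest.approx(p, rel=1e-9)
            assert fisher_exact(t.T) == pytest.approx(p, rel=1e-9)

    def test_budget_exceeded_suggests_monte_carlo(self):
        big = [[300, 300], [300, 300]]
        with pytest.raises(ValueError, match="[Mm]onte"):
            fisher_exact(big)
        p_mc = fisher_exact(big, monte_carlo=True, n_samples=2000, seed=1)
        assert 0 < p_mc <= 1

    def test_monte_carlo_close_to_exact(self):
        t = [[8, 3], [2, 9]]
        p_exact = fisher_exact(t)
        p_mc = fisher_exact(t, monte_carlo=True, n_samples=20000, seed=2)
        assert p_mc == pytest.approx(p_exact, abs=0.02)


class TestWelchAnova:
    def test_identical_means(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 0.0
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_satterthwaite_df_equal_variances(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        _, df, _ = welch_t(x, y)
        assert df == pytest.approx(58, abs=4)

    def test_matches_direct_formula_and_scipy(self):
        x, y = X10[:6], Y10[:7]
        t, df, p = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_anova_equals_pooled_t_squared_with_two_groups(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 15)
        f, df1, df2, p = one_way_anova(np.concatenate([x, y]),
                                       np.array(["a"] * 12 + ["b"] * 15))
        t_ref = sps.ttest_ind(x, y, equal_var=True)
        assert f == pytest.approx(t_ref.statistic**2, rel=1e-10)
        assert p == pytest.approx(t_ref.pvalue, rel=1e-10)

    def test_anova_matches_scipy_three_groups(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 20) for m in (0, 0.5, 1.5)]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 20)
        f, _, _, p = one_way_anova(values, labels)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_anova_detects_large_shift(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.repeat(["a", "b"], 50)
        assert one_way_anova(values, labels)[3] < 0.001

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(np.ones(10), np.repeat(["a", "b"], 5))
        with pytest.raises(ValueError):
            welch_t(np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            one_way_anova(np.arange(4.0), np.array(["a", "a", "a", "b"]))


def ls_means_oracle(y, cls, w):
    """Normal-equations LS means for the additive model, by hand."""
    levels = sorted(set(cls))
    X = np.column_stack(
        [np.ones(len(y))]
        + [(np.asarray(cls) == lev).astype(float) for lev in levels[1:]]
        + [np.asarray(w, float)]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    wbar = np.mean(w)
    out = {}
    for i, lev in enumerate(levels):
        row = np.zeros(X.shape[1])
        row[0] = 1
        if i > 0:
            row[i] = 1
        row[-1] = wbar
        out[lev] = row @ beta
    return out


class TestFeatureModel:
    def test_orthogonal_design_ls_means_equal_raw_means(self):
        # balanced groups, covariate identical across birds: no adjustment
        y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        cls = ["a", "a", "a", "b", "b", "b"]
        w = np.array([2000, 2100, 2200, 2000, 2100, 2200], float)
        m = fit_feature_model(y, cls, w)
        assert m.ls_means["a"] == pytest.approx(2.0, abs=1e-8)
        assert m.ls_means["b"] == pytest.approx(6.0, abs=1e-8)

    def test_ls_means_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 30
            cls = rng.choice(["a", "b", "c"], n)
            while len(set(cls)) < 3 or min((cls == g).sum() for g in "abc") < 4:
                cls = rng.choice(["a", "b", "c"], n)
            w = rng.normal(2300, 200, n)
            y = rng.normal(10, 2, n) + 0.002 * w
            m = fit_feature_model(y, cls, w)
            if m.interaction_included:
                continue  # oracle covers the additive model
            oracle = ls_means_oracle(y, cls, w)
            for lev, val in oracle.items():
                assert m.ls_means[lev] == pytest.approx(val, abs=1e-8)

    def test_two_groups_tukey_equals_unadjusted_t(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15)])
        cls = np.repeat(["a", "b"], 15)
        w = rng.normal(2300, 200, 30)
        m = fit_feature_model(y, cls, w)
        row = m.pairwise.iloc[0]
        p_unadj = 2 * sps.t.sf(abs(row["t"]), m.df_resid)
        assert row["p_adj"] == pytest.approx(p_unadj, rel=1e-6)

    def test_interaction_pruned_under_null(self):
        # F-test at level 0.05 should drop a truly absent interaction
        rng = np.random.default_rng(7)
        removed = 0
        reps = 100
        for _ in range(reps):
            n = 300
            cls = rng.choice(["a", "b", "c"], n, p=[0.5, 0.3, 0.2])
            w = rng.normal(2300, 200, n)
            y = (np.select([cls == "a", cls == "b"], [10.0, 12.0], 14.0)
                 + 0.001 * w + rng.normal(0, 1, n))
            m = fit_feature_model(y, cls, w)
            removed += not m.interaction_included
        assert removed >= 0.9 * reps

    def test_interaction_kept_when_real(self):
        rng = np.random.default_rng(8)
        n = 300
        cls = rng.choice(["a", "b"], n)
        w = rng.normal(2300, 200, n)
        slope = np.where(cls == "a", 0.001, 0.02)
        y = slope * w + rng.normal(0, 1, n)
        m = fit_feature_model(y, cls, w)
        assert m.interaction_included


class TestKMeans:
    def _features(self, centers, n_per, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ci, (osc, steps, ct) in enumerate(centers):
            for j in range(n_per):
                rows.append({
                    "bird_id": f"c{ci}_{j}",
                    "osc_px": rng.normal(osc, 0.05),
                    "step_count": rng.normal(steps, 0.05),
                    "completion_s": rng.normal(ct, 0.05),
                    "excluded_flag": False,
                })
        return pd.DataFrame(rows)

    def _classified(self, feats, mapping):
        return pd.DataFrame({
            "bird_id": feats["bird_id"],
            "gs_class": [mapping[b.split("_")[0]] for b in feats["bird_id"]],
            "hb_class": "HB0", "fpd_class": "FPD0", "weight_g": 2300.0,
        })

    def test_separated_blobs_recovered_exactly(self):
        feats = self._features([(5, 10, 4), (11, 15, 9), (10, 22, 22)], 12)
        cls = self._classified(feats, {"c0": "GS1", "c1": "GS2", "c2": "GS3+"})
        res = kmeans_gait_clusters(feats, cls, seed=0)
        # blob of birds with the shortest completion time is cluster A,
        # longest is B; each blob must land in exactly one cluster
        labels = res.assignments
        for prefix, expect in (("c0", "A"), ("c1", "C"), ("c2", "B")):
            got = {labels[b] for b in labels.index if b.startswith(prefix)}
            assert got == {expect}

    def test_confusion_column_sums_equal_class_sizes(self, small_population):
        feats = small_population["features"]
        cls = small_population["classified"]
        res = kmeans_gait_clusters(feats.loc[~feats.excluded_flag], cls, seed=1)
        sizes = cls[cls.bird_id.isin(res.assignments.index)]["gs_class"].value_counts()
        for g in res.confusion.columns:
            assert res.confusion[g].sum() == sizes.get(g, 0)

    def test_deterministic_given_seed(self, small_population):
        feats = small_population["features"]
        cls = small_population["classified"]
        a = kmeans_gait_clusters(feats, cls, seed=5)
        b = kmeans_gait_clusters(feats, cls, seed=5)
        assert a.assignments.equals(b.assignments)
        assert a.inertia == b.inertia

    def test_identical_points_zero_inertia(self):
        feats = pd.DataFrame({
            "bird_id": [f"b{i}" for i in range(6)],
            "osc_px": 10.0, "step_count": 14.0, "completion_s": 7.0,
            "excluded_flag": False,
        })
        cls = pd.DataFrame({"bird_id": feats["bird_id"], "gs_class": "GS1",
                            "hb_class": "HB0", "fpd_class": "FPD0",
                            "weight_g": 2300.0})
        res = kmeans_gait_clusters(feats, cls, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_too_few_birds_rejected(self):
        feats = self._features([(5, 10, 4)], 1)
        cls = self._classified(feats, {"c0": "GS1"})
        with pytest.raises(ValueError):
            kmeans_gait_clusters(feats.iloc[:2], cls, k=3)
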