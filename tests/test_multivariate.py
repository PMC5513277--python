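import numpy as np
import pandas as pd
import pytest
from scipy import stats

from songdiff import multivariate
from songdiff.multivariate import (
    DesignError,
    discriminant_analysis,
    kruskal_dunn,
    nested_anova,
    nested_manova,
    nmds,
    pca_reduce,
)


def _frame(X, pop=None, ind=None):
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])])
    if pop is not None:
        df["population_id"] = pop
    if ind is not None:
        df["individual_id"] = ind
    return df


class TestPCA:
    def test_single_dominant_direction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x + 1, -0.5 * x])
        m = pca_reduce(_frame(X))
        assert m.k == 1
        assert m.variance_fractions[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        m = pca_reduce(_frame(X))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(Z @ m.loadings @ m.loadings.T, Z, atol=1e-8)

    def test_scores_zero_mean_and_variance_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 6)) @ rng.normal(size=(6, 6))
        m = pca_reduce(_frame(X))
        S = m.scores[[c for c in m.scores.columns if c.startswith("PRIN")]]
        assert np.allclose(S.mean(0), 0, atol=1e-10)
        assert m.retained_variance == pytest.approx(
            m.eigenvalues[: m.k].sum() / len(m.feature_names))

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=30), np.ones(30), rng.normal(size=30)])
        m = pca_reduce(_frame(X))
        assert m.dropped_constant == ["v1"]
        assert len(m.feature_names) == 2

    def test_isotropic_noise_eigenvalues_near_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5000, 6))
        m = pca_reduce(_frame(X))
        assert np.all(np.abs(m.eigenvalues - 1) < 0.15)


class TestNestedAnova:
    def test_hand_computed_oracle(self):
        """2 populations x 2 individuals x 3 songs, sums of squares by hand:
        SS_pop=60.75 (df 1), SS_ind=7.5 (df 2), SS_res=8 (df 8)
        -> F_pop = 60.75/3.75 = 16.2, F_ind = 3.75/1 = 3.75."""
        y = np.array([1, 2, 3, 2, 3, 4, 5, 6, 7, 7, 8, 9], dtype=float)
        pop = np.repeat(["A", "B"], 6)
        ind = np.repeat(["a1", "a2", "b1", "b2"], 3)
        r_pop, r_ind = nested_anova(y, pop, ind)
        assert r_pop.approx_f == pytest.approx(16.2)
        assert (r_pop.df_num, r_pop.df_den) == (1, 2)
        assert r_ind.approx_f == pytest.approx(3.75)
        assert (r_ind.df_num, r_ind.df_den) == (2, 8)
        assert r_pop.pvalue == pytest.approx(stats.f.sf(16.2, 1, 2))

    def test_manova_reduces_to_anova_univariate(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=18) + np.repeat([0.0, 1.0, 3.0], 6)
        pop = np.repeat(["A", "B", "C"], 6)
        ind = np.repeat([f"i{j}" for j in range(6)], 3)
        df = pd.DataFrame({"PRIN1": y, "population_id": pop, "individual_id": ind})
        man = nested_manova(df)
        an = nested_anova(y, pop, ind)
        for m, a in zip(man, an):
            assert m.approx_f == pytest.approx(a.approx_f)
            assert m.pvalue == pytest.approx(a.pvalue)

    def test_population_null_pvalues_uniform(self):
        """With no population effect, the population-effect p-value is
        approximately uniform (type-I close to nominal)."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = rng.normal(size=24)
            pop = np.repeat(["A", "B", "C"], 8)
            ind = np.repeat([f"i{j}" for j in range(12)], 2)
            r_pop, _ = nested_anova(y, pop, ind)
            rejections += r_pop.pvalue < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_planted_population_effect_ordering(self):
        rng = np.random.default_rng(7)
        pop = np.repeat(["A", "B", "C"], 20)
        ind = np.repeat([f"i{j}" for j in range(12)], 5)
        y = rng.normal(size=60, scale=0.5) + np.repeat([0.0, 4.0, 8.0], 20)
        r_pop, r_ind = nested_anova(y, pop, ind)
        assert r_pop.approx_f > r_ind.approx_f
        assert r_pop.pvalue < 1e-4

    def test_unestimable_design_raises(self):
        y = np.arange(4, dtype=float)
        with pytest.raises(DesignError):
            nested_anova(y, np.repeat(["A", "B"], 2), np.repeat(["a", "b"], 2))


class TestDFA:
    def test_separated_clouds(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.1, (30, 3)), rng.normal(5, 0.1, (30, 3))])
        df = _frame(X, pop=np.repeat(["A", "B"], 30))
        m = discriminant_analysis(df, score_cols=["v0", "v1", "v2"])
        assert m.correct_rate == 1.0
        assert m.canonical_correlations[0] > 0.99

    def test_shuffled_labels_chance_rate(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 4))
        df = _frame(X, pop=rng.permutation(np.repeat(["A", "B", "C"], 100)))
        m = discriminant_analysis(df, score_cols=[f"v{i}" for i in range(4)])
        assert abs(m.correct_rate - 1 / 3) < 0.12

    def test_canonical_correlations_affine_invariant(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(90, 4)) + np.repeat(
            rng.normal(0, 2, (3, 4)), 30, axis=0)
        pop = np.repeat(["A", "B", "C"], 30)
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        m1 = discriminant_analysis(_frame(X, pop=pop),
                                   score_cols=[f"v{i}" for i in range(4)])
        m2 = discriminant_analysis(_frame(X @ M + 7.0, pop=pop),
                                   score_cols=[f"v{i}" for i in range(4)])
        assert m1.canonical_correlations == pytest.approx(
            m2.canonical_correlations, abs=1e-8)

    def test_axis_count_bounded(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 5))
        m = discriminant_analysis(_frame(X, pop=np.repeat(["A", "B"], 30)),
                                  score_cols=[f"v{i}" for i in range(5)])
        assert len(m.canonical_correlations) == 1  # min(5, 2-1)


class TestNMDS:
    def test_planar_data_near_zero_stress(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 2))
        res = nmds(_frame(X), feature_names=["v0", "v1"], restarts=8, seed=1)
        assert res.stress < 0.05

    def test_seeded_determinism(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 4))
        r1 = nmds(_frame(X), restarts=4, seed=3)
        r2 = nmds(_frame(X), restarts=4, seed=3)
        assert r1.stress == pytest.approx(r2.stress)
        assert np.allclose(r1.configuration, r2.configuration)

    def test_degenerate_equal_distances_flagged(self):
        D = np.ones((6, 6)) - np.eye(6)
        res = nmds(D, precomputed=True, restarts=2, seed=0)
        assert res.degenerate

    def test_stress_nonnegative(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(15, 6))
        assert nmds(_frame(X), restarts=3, seed=5).stress >= 0


class TestKruskalDunn:
    def test_identical_distributions_zero(self):
        v = np.tile([1.0, 1.0, 1.0], 3)
        r = kruskal_dunn(v, np.repeat(["A", "B", "C"], 3))
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_hand_ranked_oracle_n9(self):
        """Three groups {1,2,3},{4,5,6},{7,8,9}: ranks are the values,
        H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2) = 7.2; Dunn z for the
        extreme pair = (2-8)/sqrt((9*10/12)*(2/3)) = -6/sqrt(5)."""
        v = np.arange(1.0, 10.0)
        g = np.repeat(["A", "B", "C"], 3)
        r = kruskal_dunn(v, g)
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2
        row = r.dunn[(r.dunn.group_a == "A") & (r.dunn.group_b == "C")].iloc[0]
        assert row.z == pytest.approx(-6 / np.sqrt(5))
        assert row.p_bonferroni == pytest.approx(min(1, 3 * row.p_raw))

    def test_six_groups_df_five(self):
        rng = np.random.default_rng(15)
        v = rng.random(60)
        r = kruskal_dunn(v, np.repeat(list("ABCDEF"), 10))
        assert r.df == 5
        assert len(r.dunn) == 15

    def test_matches_scipy_statistic(self):
        rng = np.random.default_rng(16)
        v = rng.normal(size=40)
        g = rng.choice(["A", "B", "C", "D"], size=40)
        r = kruskal_dunn(v, g)
        expected = stats.kruskal(*[v[g == x] for x in np.unique(g)])
        assert r.statistic == pytest.approx(expected.statistic)
        assert r.pvalue == pytest.approx(expected.pvalue)
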