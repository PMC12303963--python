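"""Healing-rating screening, factor analysis, clustering, correlation.

Principal-axis factoring is cross-checked against the independent
statsmodels implementation; varimax against an inverted known rotation;
the Pearson table against a hand-computed five-point example.
"""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromascape.psych import (contribution_rates, correlate_metrics_factors,
                               factor_scores, image_factor_scores,
                               item_correlation_matrix, kaiser_n_factors,
                               principal_axis_factor,
                               printed_contribution_rates, rotate_solution,
                               screen_loadings, select_samples,
                               summarize_healing_ratings, varimax_rotate,
                               ward_cluster)
from oracles import best_congruences, tucker


# ---------------------------------------------------------------------------
# healing-rating screening

class TestHealingSummaries:
    def test_basic_statistics(self):
        (s,) = summarize_healing_ratings({"a": [5, 6, 6, 7]})
        assert s.mean == 6.0 and s.median == 6.0 and s.n_raters == 4

    def test_even_median_midpoint(self):
        (s,) = summarize_healing_ratings({"a": [1, 7]})
        assert s.median == 4.0 and s.mean == 4.0

    def test_sample_sd(self):
        (s,) = summarize_healing_ratings({"a": [5, 5, 6, 7, 7]})
        assert s.mean == 6.0 and s.median == 6.0
        assert s.sd == pytest.approx(1.0)

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            summarize_healing_ratings({"a": [5, 8]})
        with pytest.raises(ValueError):
            summarize_healing_ratings({"a": [0, 5]})


class TestSelectSamples:
    def _summary(self, mean, median, sd):
        from chromascape.psych import HealingRatingSummary
        return HealingRatingSummary("x", 23, mean, median, sd)

    @pytest.mark.parametrize("mean,median,sd,expected", [
        (5.225, 5.5, 0.9, True),    # comfortably above thresholds
        (5.0, 5.0, 1.19, True),     # inclusive mean/median floors
        (5.0, 5.0, 1.20, False),    # sd bound is strict
        (4.99, 5.5, 0.5, False),    # mean below floor
        (5.3, 4.5, 0.8, False),     # median below floor
    ])
    def test_boundary_semantics(self, mean, median, sd, expected):
        got = select_samples([self._summary(mean, median, sd)])
        assert (got == ["x"]) is expected


# ---------------------------------------------------------------------------
# item correlations

class TestItemCorrelation:
    def test_duplicated_item_r_one(self, rng):
        x = rng.standard_normal(100)
        data = np.column_stack([x, x, rng.standard_normal(100)])
        corr = item_correlation_matrix(data)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(99)
        data = rng.standard_normal((10000, 6))
        corr = item_correlation_matrix(data).to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_zero_variance_item_named(self):
        data = np.column_stack([np.ones(10), np.arange(10)])
        with pytest.raises(ValueError, match="itemA"):
            item_correlation_matrix(data, ["itemA", "itemB"])


# ---------------------------------------------------------------------------
# principal-axis factoring

class TestPrincipalAxis:
    def test_identity_retains_zero_factors(self):
        sol = principal_axis_factor(np.eye(24))
        assert sol.n_factors == 0
        assert sol.loadings.shape == (24, 0)

    def test_one_factor_closed_form(self):
        lam = 0.8
        R = np.full((24, 24), lam * lam)
        np.fill_diagonal(R, 1.0)
        sol = principal_axis_factor(R, n_factors=1)
        np.testing.assert_allclose(np.abs(sol.loadings[:, 0]), lam,
                                   atol=0.01)
        np.testing.assert_allclose(sol.communalities, lam * lam, atol=0.01)

    def test_three_factor_recovery_tucker(self):
        """Planted 3-orthogonal-factor data (24 items, loadings 0.7,
        n=500): mean Tucker congruence after varimax >= 0.95 over
        20 seeds."""
        L = np.zeros((24, 3))
        for i in range(24):
            L[i, i % 3] = 0.7
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            F = rng.standard_normal((500, 3))
            X = F @ L.T + rng.standard_normal((500, 24)) * math.sqrt(0.51)
            sol = rotate_solution(
                principal_axis_factor(item_correlation_matrix(X),
                                      n_factors=3))
            means.append(np.mean(best_congruences(L, sol.loadings)))
        assert np.mean(means) >= 0.95

    def test_matches_statsmodels_oracle(self, rng):
        """Loadings agree with the independent statsmodels principal-axis
        implementation up to column sign."""
        statsmodels = pytest.importorskip("statsmodels.multivariate.factor")
        L = np.zeros((12, 3))
        for i in range(12):
            L[i, i % 3] = 0.7
        X = (rng.standard_normal((400, 3)) @ L.T
             + rng.standard_normal((400, 12)) * 0.7)
        R = item_correlation_matrix(X).to_numpy()
        mine = principal_axis_factor(R, n_factors=3).loadings
        ref = statsmodels.Factor(corr=R, n_factor=3, method="pa",
                                 smc=True).fit().loadings
        for j in range(3):
            diff = min(min(np.abs(mine[:, j] - ref[:, m]).max(),
                           np.abs(mine[:, j] + ref[:, m]).max())
                       for m in range(3))
            assert diff < 1e-4

    def test_kaiser_rule_on_unreduced_matrix(self):
        R = np.full((10, 10), 0.5)
        np.fill_diagonal(R, 1.0)
        assert kaiser_n_factors(R) == 1  # one dominant eigenvalue 5.5

    def test_contribution_rate_arithmetic(self):
        contrib, cum = contribution_rates([3.0, 1.5], 24)
        np.testing.assert_allclose(contrib, [12.5, 6.25])
        np.testing.assert_allclose(cum, [12.5, 18.75])

    def test_printed_cumulative_rounding(self):
        """Fixed-point half-up cumulative contribution over a published
        six-eigenvalue sequence lands on 64.313, not the float 64.312."""
        ev = ["3.157", "2.839", "2.756", "2.538", "2.170", "1.975"]
        contrib, cum = printed_contribution_rates(ev, 24)
        assert cum[-1] == 64.313
        assert contrib[0] == pytest.approx(100 * 3.157 / 24, abs=5e-4)


class TestVarimax:
    def test_simple_structure_fixed_point(self):
        S = np.zeros((10, 2))
        S[:5, 0] = 0.8
        S[5:, 1] = 0.8
        rotated, T = varimax_rotate(S)
        np.testing.assert_allclose(rotated, S, atol=1e-10)

    def test_inverts_known_45_degree_rotation(self):
        S = np.zeros((10, 2))
        S[:5, 0] = 0.8
        S[5:, 1] = 0.8
        th = math.pi / 4
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        rotated, _ = varimax_rotate(S @ R)
        err = min(np.abs(rotated - S).max(),
                  np.abs(rotated - S[:, ::-1]).max())
        assert err < 1e-4

    def test_rotation_matrix_orthonormal(self, rng):
        A = rng.standard_normal((15, 4)) * 0.5
        rotated, T = varimax_rotate(A)
        np.testing.assert_allclose(T.T @ T, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(A @ T, rotated, atol=1e-10)

    def test_communalities_preserved(self, rng):
        A = rng.standard_normal((20, 3)) * 0.5
        rotated, _ = varimax_rotate(A)
        np.testing.assert_allclose((rotated ** 2).sum(axis=1),
                                   (A ** 2).sum(axis=1), atol=1e-8)

    def test_single_factor_noop(self):
        A = np.linspace(0.2, 0.9, 8).reshape(-1, 1)
        rotated, T = varimax_rotate(A)
        np.testing.assert_array_equal(rotated, A)
        np.testing.assert_array_equal(T, np.eye(1))


class TestScreenLoadings:
    def _solution(self, loadings, labels):
        from chromascape.psych import FactorSolution
        L = np.asarray(loadings, dtype=float)
        ev = (L ** 2).sum(axis=0)
        c, cum = contribution_rates(ev, L.shape[0])
        return FactorSolution(L, ev, c, cum, (L ** 2).sum(axis=1),
                              list(labels))

    def test_strong_simple_item_retained(self):
        sol = self._solution([[0.849, 0.125], [0.2, 0.7]], ["a", "b"])
        retained, assign = screen_loadings(sol)
        assert "a" in retained and assign["a"] == 0

    def test_weak_item_dropped(self):
        sol = self._solution([[0.39, 0.1], [0.2, 0.7]], ["a", "b"])
        retained, _ = screen_loadings(sol)
        assert "a" not in retained

    def test_crossloader_dropped(self):
        sol = self._solution([[0.55, 0.45], [0.2, 0.7]], ["a", "b"])
        retained, _ = screen_loadings(sol)
        assert "a" not in retained


class TestFactorScores:
    def test_noisefree_scores_correlate_perfectly(self, rng):
        L = np.zeros((12, 2))
        L[:6, 0] = 0.9
        L[6:, 1] = 0.9
        F = rng.standard_normal((300, 2))
        X = F @ L.T  # rank-2, noise-free
        sol = rotate_solution(principal_axis_factor(
            np.corrcoef(X, rowvar=False), n_factors=2))
        S = factor_scores(X, sol)
        for j in range(2):
            r = max(abs(np.corrcoef(F[:, j], S[:, m])[0, 1])
                    for m in range(2))
            assert r > 0.999

    def test_scores_centered(self, rng):
        X = rng.standard_normal((200, 8))
        sol = principal_axis_factor(np.corrcoef(X, rowvar=False),
                                    n_factors=2)
        S = factor_scores(X, sol)
        np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-10)

    def test_planted_two_factor_recovery(self):
        rng = np.random.default_rng(4)
        L = np.zeros((12, 2))
        L[:6, 0] = 0.8
        L[6:, 1] = 0.8
        F = rng.standard_normal((500, 2))
        X = F @ L.T + rng.standard_normal((500, 12)) * 0.6
        sol = rotate_solution(principal_axis_factor(
            np.corrcoef(X, rowvar=False), n_factors=2))
        S = factor_scores(X, sol)
        for j in range(2):
            r = max(abs(np.corrcoef(F[:, j], S[:, m])[0, 1])
                    for m in range(2))
            assert r >= 0.9

    def test_image_scores_z_scored(self, rng):
        scores = rng.standard_normal((100, 3))
        ids = [f"img{i % 10}" for i in range(100)]
        z = image_factor_scores(scores, ids)
        assert z.shape == (10, 3)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# clustering

class TestWardCluster:
    def test_two_planted_clouds_perfect_partition(self, rng):
        X = np.vstack([rng.normal((-10, 0), 0.1, size=(10, 2)),
                       rng.normal((10, 0), 0.1, size=(10, 2))])
        truth = [0] * 10 + [1] * 10
        df = pd.DataFrame(X, index=[f"i{j}" for j in range(20)],
                          columns=["factor1", "factor2"])
        sol = ward_cluster(df, k=2)
        labels = [sol.assignments[f"i{j}"] for j in range(20)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_eight_planted_centroids_ari(self, rng):
        """42 points around 8 well-separated centroids in 6-dim factor
        space are recovered with ARI >= 0.9."""
        centers = rng.standard_normal((8, 6)) * 6
        truth = np.arange(42) % 8  # cluster sizes 6,6,5,5,5,5,5,5
        X = centers[truth] + rng.standard_normal((42, 6)) * 0.3
        df = pd.DataFrame(X, index=[f"i{j}" for j in range(42)],
                          columns=[f"factor{k+1}" for k in range(6)])
        sol = ward_cluster(df, k=8)
        labels = [sol.assignments[f"i{j}"] for j in range(42)]
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert sol.profile.shape == (8, 6)

    def test_merge_heights_non_decreasing(self, rng):
        df = pd.DataFrame(rng.standard_normal((30, 4)))
        sol = ward_cluster(df, k=3)
        assert (np.diff(sol.merge_heights) >= -1e-12).all()

    def test_k_one_silhouette_nan(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 3)))
        sol = ward_cluster(df, k=1)
        assert sol.k == 1 and math.isnan(sol.mean_silhouette)

    def test_k_exceeding_n_rejected(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 2)))
        with pytest.raises(ValueError):
            ward_cluster(df, k=6)

    def test_auto_k_picks_planted_count(self, rng):
        centers = np.array([[-10, 0], [10, 0], [0, 10]], dtype=float)
        truth = np.repeat(np.arange(3), 10)
        X = centers[truth] + rng.standard_normal((30, 2)) * 0.2
        sol = ward_cluster(pd.DataFrame(X), k=None)
        assert sol.k == 3


# ---------------------------------------------------------------------------
# metric-factor correlation

class TestCorrelation:
    def test_hand_computed_five_points_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand computation: sum xy = 51, mean 3/3, ssx = ssy = 10 -> r = 0.8
        m = pd.DataFrame({"m": x}, index=list("abcde"))
        f = pd.DataFrame({"factor1": y}, index=list("abcde"))
        tab = correlate_metrics_factors(m, f)
        assert tab.r.loc["m", "factor1"] == pytest.approx(0.8, abs=1e-12)

    def test_identical_columns_r_one(self):
        x = np.linspace(0, 1, 10)
        m = pd.DataFrame({"m": x})
        f = pd.DataFrame({"factor1": x})
        tab = correlate_metrics_factors(m, f)
        assert tab.r.loc["m", "factor1"] == pytest.approx(1.0)
        assert tab.flags.loc["m", "factor1"] == "**"

    def test_planted_r_recovered_at_large_n(self):
        rng = np.random.default_rng(6)
        n = 10000
        x = rng.standard_normal(n)
        y = 0.45 * x + math.sqrt(1 - 0.45 ** 2) * rng.standard_normal(n)
        tab = correlate_metrics_factors(pd.DataFrame({"m": x}),
                                        pd.DataFrame({"factor1": y}))
        assert tab.r.loc["m", "factor1"] == pytest.approx(0.45, abs=0.03)

    def test_null_column_unflagged(self):
        rng = np.random.default_rng(7)
        n = 10000
        tab = correlate_metrics_factors(
            pd.DataFrame({"m": rng.standard_normal(n)}),
            pd.DataFrame({"factor1": rng.standard_normal(n)}))
        assert abs(tab.r.loc["m", "factor1"]) < 0.05
        assert tab.flags.loc["m", "factor1"] == ""

    def test_constant_metric_gives_na(self, rng):
        m = pd.DataFrame({"m": np.ones(10)})
        f = pd.DataFrame({"factor1": rng.standard_normal(10)})
        tab = correlate_metrics_factors(m, f)
        assert math.isnan(tab.r.loc["m", "factor1"])
        assert tab.flags.loc["m", "factor1"] == "NA"

    def test_nan_cells_use_pairwise_complete(self, rng):
        x = rng.standard_normal(20)
        xm = x.copy()
        xm[:5] = np.nan
        m = pd.DataFrame({"m": xm})
        f = pd.DataFrame({"factor1": x})
        tab = correlate_metrics_factors(m, f)
        assert tab.n.loc["m", "factor1"] == 15
        assert tab.r.loc["m", "factor1"] == pytest.approx(1.0)
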