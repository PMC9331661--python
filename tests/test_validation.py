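"""Procrustes CV, ROC analysis, and the nonparametric group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aromet.preprocess import autoscale
from aromet.simca import classify, distances, fit_pca, fit_simca
from aromet.validation import (
    holm_adjust,
    kruskal_wallis,
    make_segments,
    mann_whitney,
    procrustes_cv,
    roc,
)


def classical_cv_distances(X, A, segments):
    """Independent oracle: classical segment-wise cross-validation distances."""
    n = X.shape[0]
    h = np.zeros(n)
    v = np.zeros(n)
    for seg in segments:
        rest = [i for i in range(n) if i not in seg]
        local = fit_pca(X[rest], A)
        for i in seg:
            t = local.loadings.T @ X[i]
            h[i] = float(np.sum(t**2 / local.eigenvalues))
            e = X[i] - local.loadings @ t
            v[i] = float(e @ e)
    return h, v


class TestProcrustesCV:
    def test_full_rank_pseudo_set_has_zero_orthogonal_distance(self, rng):
        Xs, _ = autoscale(rng.normal(size=(12, 4)))
        pv = procrustes_cv(Xs, 4)
        model = fit_pca(Xs, 4)
        _, v = distances(model, pv.matrix, scaled=True)
        np.testing.assert_allclose(v, 0.0, atol=1e-16)

    @pytest.mark.parametrize("scheme", ["loo", 5])
    def test_pseudo_distances_match_classical_cv(self, rng, scheme):
        Xs, _ = autoscale(rng.normal(size=(30, 8)) * rng.uniform(0.5, 3, 8))
        pv = procrustes_cv(Xs, 3, segments=scheme)
        model = fit_pca(Xs, 3)
        h_pv, v_pv = distances(model, pv.matrix, scaled=True)
        h_cv, v_cv = classical_cv_distances(Xs, 3, pv.segments)
        assert np.median(np.abs(h_pv - h_cv) / h_cv) < 0.10
        assert np.median(np.abs(v_pv - v_cv) / v_cv) < 0.10

    def test_pseudo_set_shape_and_partition(self, rng):
        Xs, _ = autoscale(rng.normal(size=(20, 5)))
        pv = procrustes_cv(Xs, 2, segments=4)
        assert pv.matrix.shape == Xs.shape
        assert sorted(i for s in pv.segments for i in s) == list(range(20))

    def test_fn_rate_on_pseudo_set_near_alpha(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 8)) * np.array([3, 2, 1.5, 1, 1, 0.5, 0.4, 0.3])
        model = fit_simca(X, n_components=3, alpha=0.05)
        Xs, _ = autoscale(X, model.pca.scaling)
        pv = procrustes_cv(Xs, 3, segments=10)
        accepted, _ = classify(model, pv.matrix, scaled=True)
        # binomial 99% band around alpha=0.05 at n=400
        assert 0.022 <= np.mean(~accepted) <= 0.078

    def test_segment_too_small_for_components_rejected(self, rng):
        Xs, _ = autoscale(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="too few rows"):
            procrustes_cv(Xs, 4, segments="loo")

    def test_make_segments_schemes(self):
        assert make_segments(4, "loo") == [[0], [1], [2], [3]]
        assert make_segments(5, 2) == [[0, 1], [2, 3, 4]]
        with pytest.raises(ValueError):
            make_segments(3, 7)


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([1, 2, 3, 4], [False, False, True, True])
        assert curve.auc == 1.0
        assert curve.fpr[0] == 0 and curve.tpr[-1] == 1

    def test_interleaved_pairs(self):
        # pair counting over all 4 (pos, neg) pairs: wins {2>1, 4>1, 4>3} = 3/4
        curve = roc([1, 2, 3, 4], [False, True, False, True])
        assert curve.auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        curve = roc([2.0] * 6, [True, False] * 3)
        assert curve.auc == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roc([1.0, 2.0], [True, True])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 40))
    def test_trapezoid_equals_pair_counting_on_random_scores(self, seed, n):
        r = np.random.default_rng(seed)
        scores = np.round(r.normal(size=n), 1)  # rounding forces ties
        labels = r.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        curve = roc(scores, labels)  # raises internally if the two disagree
        pos, neg = scores[labels], scores[~labels]
        auc_bf = np.mean([
            1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
        ])
        assert curve.auc == pytest.approx(auc_bf)

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        curve = roc(scores, labels)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


class TestMannWhitney:
    def test_exact_small_sample(self):
        # enumeration over C(4,2)=6 assignments: U in {0,4} in 2 of 6
        U, p = mann_whitney([1, 2], [3, 4])
        assert U == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_large_separated_groups_tiny_p(self):
        r = np.random.default_rng(9)
        x = r.normal(0, 1, 100)
        y = r.normal(3, 1, 100)
        U, p = mann_whitney(x, y)
        assert p < 1e-6
        # orientation: U counts x-over-y wins
        assert U < 100 * 100 / 2

    def test_asymptotic_branch_matches_scipy(self):
        r = np.random.default_rng(2)
        x, y = r.normal(size=30), r.normal(0.5, 1, size=25)
        U, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_no_difference(self):
        H, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert H == 0.0 and p == 1.0

    def test_hand_traced_three_group_example(self):
        # groups {1,2}, {3,4}, {5,6}: ranks 1..6, no ties;
        # H = 12/(n(n+1)) * sum n_i (Rbar_i - (n+1)/2)^2
        #   = 12/42 * (2*(1.5-3.5)^2 + 2*(3.5-3.5)^2 + 2*(5.5-3.5)^2) = 32/7
        H, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert H == pytest.approx(32 / 7)
        assert p == pytest.approx(float(stats.chi2.sf(32 / 7, 2)))

    def test_two_groups_agrees_with_mann_whitney_asymptotically(self):
        r = np.random.default_rng(3)
        x, y = r.normal(size=200), r.normal(0.3, 1, size=200)
        _, p_kw = kruskal_wallis([x, y])
        _, p_mw = mann_whitney(x, y)
        assert p_kw == pytest.approx(p_mw, rel=0.05)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestHolmAdjust:
    def test_hand_traced_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 5000), m=st.integers(1, 12))
    def test_adjusted_at_least_raw_and_order_preserving(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
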