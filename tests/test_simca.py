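"""DD-SIMCA core: PCA, distances, chi-squared DOF estimation, classification."""

import numpy as np
import pytest
from scipy import stats

from aromet.preprocess import autoscale
from aromet.simca import (
    classify,
    distances,
    estimate_dof,
    false_negative_rate,
    fit_pca,
    fit_simca,
    full_distance,
    model_from_json,
    model_to_json,
    univariate_cutoff,
    DistanceParams,
)


def brute_force_distances(loadings, eigenvalues, X):
    """Independent projection oracle: explicit per-sample matrix arithmetic."""
    h = np.empty(len(X))
    v = np.empty(len(X))
    for i, x in enumerate(X):
        t = np.array([np.dot(loadings[:, a], x) for a in range(loadings.shape[1])])
        h[i] = sum(t[a] ** 2 / eigenvalues[a] for a in range(len(t)))
        recon = sum(t[a] * loadings[:, a] for a in range(len(t)))
        v[i] = np.dot(x - recon, x - recon)
    return h, v


class TestFitPca:
    def test_exact_rank_one_gives_zero_residuals(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=5))
        model = fit_pca(X, 1)
        _, v = distances(model, X, scaled=True)
        np.testing.assert_allclose(v, 0.0, atol=1e-18)

    def test_eigenvalues_are_score_variances(self, rng):
        X, _ = autoscale(rng.normal(size=(30, 6)))
        model = fit_pca(X, 3)
        scores = X @ model.loadings
        np.testing.assert_allclose(
            model.eigenvalues, scores.var(axis=0, ddof=1), rtol=1e-10
        )

    def test_full_rank_eigenvalue_sum_is_p(self, rng):
        # autoscaled data: each variable contributes unit variance
        X, _ = autoscale(rng.normal(size=(40, 5)))
        model = fit_pca(X, 5)
        assert model.eigenvalues.sum() == pytest.approx(5.0, rel=1e-10)

    def test_reconstruction_error_nonincreasing_in_components(self, rng):
        X, _ = autoscale(rng.normal(size=(25, 6)))
        errors = []
        for A in range(1, 6):
            _, v = distances(fit_pca(X, A), X, scaled=True)
            errors.append(v.sum())
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_components_beyond_rank_rejected(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=4))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 2)


class TestDistances:
    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(10, 8)) * rng.uniform(0.5, 3, size=8)
        Xs, _ = autoscale(X)
        model = fit_pca(Xs, 3)
        h, v = distances(model, Xs, scaled=True)
        h_bf, v_bf = brute_force_distances(model.loadings, model.eigenvalues, Xs)
        np.testing.assert_allclose(h, h_bf, rtol=1e-10)
        np.testing.assert_allclose(v, v_bf, rtol=1e-10)

    def test_calibration_mean_has_zero_distances(self, rng):
        X = rng.normal(2.0, 1.5, size=(20, 5))
        model = fit_simca(X, n_components=2, alpha=0.05)
        h, v = distances(model.pca, X.mean(axis=0, keepdims=True))
        assert h[0] == pytest.approx(0.0, abs=1e-18)
        assert v[0] == pytest.approx(0.0, abs=1e-18)

    def test_sample_in_loading_subspace_has_zero_orthogonal_distance(self, rng):
        Xs, _ = autoscale(rng.normal(size=(15, 6)))
        model = fit_pca(Xs, 2)
        x = (model.loadings @ np.array([1.3, -0.7]))[None, :]
        _, v = distances(model, x, scaled=True)
        assert v[0] == pytest.approx(0.0, abs=1e-18)

    def test_variable_mismatch_rejected(self, rng):
        Xs, _ = autoscale(rng.normal(size=(15, 6)))
        model = fit_pca(Xs, 2)
        with pytest.raises(ValueError, match="mismatch"):
            distances(model, np.zeros((2, 5)), scaled=True)


class TestEstimateDof:
    def test_monte_carlo_recovery_of_generating_dof(self):
        rng = np.random.default_rng(123)
        for N in [1, 2, 3, 5, 8, 13, 21, 30]:
            d = 2.5 * rng.chisquare(N, size=10_000) / N
            _, N_hat = estimate_dof(d)
            assert abs(N_hat - N) <= 1, f"N={N} estimated as {N_hat}"

    def test_scale_estimate_is_mean(self, rng):
        d = rng.chisquare(4, 500)
        d0, _ = estimate_dof(d)
        assert d0 == pytest.approx(d.mean())

    def test_heavy_spread_clips_to_one(self, rng):
        d = np.r_[np.zeros(50), [1000.0]]
        _, N = estimate_dof(d)
        assert N == 1

    def test_near_constant_clips_to_250(self):
        d = 1.0 + 1e-9 * np.arange(10)
        _, N = estimate_dof(d)
        assert N == 250

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance|degenerate"):
            estimate_dof(np.ones(10))
        with pytest.raises(ValueError, match="at least 3"):
            estimate_dof([1.0, 2.0])


class TestFullDistance:
    params = DistanceParams(h0=2.0, Nh=1, v0=3.0, Nv=2, alpha=0.01,
                            f_crit=float(stats.chi2.ppf(0.99, 3)))

    def test_unit_scaled_case(self):
        assert full_distance(2.0, 3.0, self.params) == pytest.approx(3.0)  # Nh + Nv

    def test_center_is_zero(self):
        assert full_distance(0.0, 0.0, self.params) == 0.0

    def test_direct_arithmetic(self):
        # Nh=1 with h/h0=2 plus Nv=2 with v/v0=3 -> 1*2 + 2*3 = 8
        assert full_distance(4.0, 9.0, self.params) == pytest.approx(8.0)

    def test_monotone_in_each_distance(self, rng):
        h, v = rng.uniform(0, 5, 50), rng.uniform(0, 5, 50)
        f = full_distance(h, v, self.params)
        assert np.all(full_distance(h + 0.1, v, self.params) > f)
        assert np.all(full_distance(h, v + 0.1, self.params) > f)


class TestFitSimcaAndClassify:
    def test_cutoff_is_chi2_quantile(self, rng):
        X = rng.normal(size=(60, 8)) * np.array([3, 2, 1.5, 1, 1, 0.5, 0.4, 0.3])
        model = fit_simca(X, n_components=3, alpha=0.01)
        dof = model.dist.Nh + model.dist.Nv
        assert model.dist.f_crit == pytest.approx(float(stats.chi2.ppf(0.99, dof)))
        if dof == 3:
            assert model.dist.f_crit == pytest.approx(11.345, abs=1e-3)

    def test_calibration_fn_rate_near_alpha_for_study_sized_set(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(88, 8)) * np.array([3, 2, 1.5, 1, 1, 0.5, 0.4, 0.3])
        model = fit_simca(X, n_components=3, alpha=0.01)
        accepted, _ = classify(model, X)
        assert 0.0 <= false_negative_rate(accepted) <= 0.05

    def test_center_accepted_extreme_rejected(self, rng):
        X = rng.lognormal(0.5, 0.4, size=(50, 8))
        model = fit_simca(X, n_components=3, alpha=0.01)
        accepted_center, f_center = classify(model, X.mean(axis=0, keepdims=True))
        assert accepted_center[0] and f_center[0] <= model.dist.f_crit
        spike = X.mean(axis=0, keepdims=True).copy()
        spike[0, 0] *= 100
        accepted_spike, f_spike = classify(model, spike)
        assert not accepted_spike[0] and f_spike[0] > model.dist.f_crit

    def test_one_rejection_in_59_reports_rate_0017(self):
        accepted = np.ones(59, dtype=bool)
        accepted[17] = False
        assert round(false_negative_rate(accepted), 3) == 0.017

    def test_refit_without_one_variable_still_classifies(self, rng):
        X = rng.lognormal(0, 0.3, size=(40, 8))
        variables = [f"a{j}" for j in range(8)]
        model8 = fit_simca(X, 3, 0.01, variables)
        model7 = fit_simca(X[:, :7], 3, 0.01, variables[:7])
        assert len(model7.variables) == 7 and len(model8.variables) == 8
        acc, f = classify(model7, X[:5, :7])
        assert f.shape == (5,)

    def test_scale_equivariance_of_classification(self, rng):
        X = rng.lognormal(0, 0.4, size=(45, 8))
        Xnew = rng.lognormal(0, 0.4, size=(30, 8))
        model = fit_simca(X, 3, 0.01)
        acc1, f1 = classify(model, Xnew)
        X2, Xnew2 = X.copy(), Xnew.copy()
        X2[:, 2] *= 37.0
        Xnew2[:, 2] *= 37.0
        model2 = fit_simca(X2, 3, 0.01)
        acc2, f2 = classify(model2, Xnew2)
        np.testing.assert_allclose(f1, f2, rtol=1e-8)
        assert np.array_equal(acc1, acc2)

    def test_larger_alpha_shrinks_acceptance_region(self, rng):
        X = rng.normal(size=(50, 6))
        f_crits = [fit_simca(X, 2, a).dist.f_crit for a in (0.001, 0.01, 0.05, 0.2)]
        assert all(a > b for a, b in zip(f_crits, f_crits[1:]))

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(30, 5)) + 5
        model = fit_simca(X, 2, 0.01, variables=list("abcde"))
        restored = model_from_json(model_to_json(model))
        assert restored.variables == model.variables
        _, f1 = classify(model, X[:4])
        _, f2 = classify(restored, X[:4])
        np.testing.assert_allclose(f1, f2)


class TestUnivariateCutoff:
    def test_exceedance_rate_matches_alpha(self):
        rng = np.random.default_rng(7)
        d0, N = 3.0, 6
        cal = d0 * rng.chisquare(N, 2000) / N
        cut = univariate_cutoff(cal, alpha=0.05)
        fresh = d0 * rng.chisquare(N, 20_000) / N
        assert np.mean(fresh > cut) == pytest.approx(0.05, abs=0.012)

    def test_alpha_near_one_rejects_everything(self, rng):
        vals = rng.lognormal(1, 0.4, 200)
        cut = univariate_cutoff(vals, alpha=0.999)
        assert np.mean(vals > cut) > 0.95

    def test_apache_cutoff_is_fixed_clinical_rule(self):
        from aromet.pipeline import APACHE_CUTOFF

        assert APACHE_CUTOFF == 19  # negative prognosis from 20 points
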