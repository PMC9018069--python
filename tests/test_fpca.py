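"""Spline smoothing with GCV, multivariate functional PCA, rank tests."""

import numpy as np
import pytest
from scipy.interpolate import make_smoothing_spline
from statsmodels.stats.multitest import multipletests

from manex import fpca


class TestSmoother:
    def test_reproduces_a_line(self):
        x = np.arange(50.0)
        c = fpca.smooth_curve(2.0 * x)
        assert np.sum((c.values - 2.0 * x) ** 2) < 1e-8

    def test_matches_reference_smoothing_spline(self, rng):
        """Fixed-penalty fits agree with scipy's smoothing spline."""
        x = np.arange(60.0)
        y = np.sin(x / 9) + rng.normal(0, 0.3, 60)
        sm = fpca.SplineSmoother(x)
        for lam in (0.5, 50.0, 5000.0):
            mine = sm.fit(y, lam=lam).values
            ref = make_smoothing_spline(x, y, lam=lam)(x)
            np.testing.assert_allclose(mine, ref, atol=1e-9)

    def test_infinite_penalty_limit_is_least_squares_line(self, rng):
        x = np.arange(40.0)
        y = 1.5 * x - 3 + rng.normal(0, 1, 40)
        fit = fpca.SplineSmoother(x).fit(y, lam=1e12).values
        coef = np.polyfit(x, y, 1)
        np.testing.assert_allclose(fit, np.polyval(coef, x), atol=1e-4)

    def test_gcv_penalizes_pure_noise_harder(self, rng):
        x = np.arange(80.0)
        noise = rng.normal(0, 1, 80)
        signal = np.sqrt(10.0) * np.sin(2 * np.pi * x / 80)  # SNR 10 in variance
        sm = fpca.SplineSmoother(x)
        lam_noise = sm.fit(noise).gcv_lambda
        lam_signal = sm.fit(signal + noise).gcv_lambda
        assert lam_noise > lam_signal

    def test_constant_input_returns_constant_at_max_penalty(self):
        c = fpca.smooth_curve(np.full(20, 3.3))
        np.testing.assert_allclose(c.values, 3.3)
        assert c.gcv_lambda == fpca.DEFAULT_LAMBDAS[-1]

    def test_spline_evaluates_to_fitted_values(self, rng):
        x = np.arange(30.0)
        y = rng.normal(0, 1, 30)
        c = fpca.smooth_curve(y)
        np.testing.assert_allclose(c(x), c.values, atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fpca.smooth_curve(np.arange(5.0))


def planted_curves(rng, n=50, scale=2.0, grid=None):
    g = grid if grid is not None else np.linspace(0, 1, 60)
    phi = [np.sin(2 * np.pi * g), np.cos(2 * np.pi * g), g - 0.5, 0.3 + 0 * g]
    nrm = np.sqrt(sum(np.trapezoid(p**2, g) for p in phi))
    phi = [p / nrm for p in phi]
    mean = [np.sin(np.pi * g)] * 4
    s = rng.normal(0, scale, n)
    curves = [[mean[e] + s[i] * phi[e] for e in range(4)] for i in range(n)]
    return curves, phi, s, g


class TestMfpca:
    def test_recovers_planted_component(self, rng):
        curves, phi, s, g = planted_curves(rng)
        mf = fpca.mfpca(curves, K=3, grid=g)
        flat = np.concatenate([mf.components[0][e] for e in range(4)])
        truth = np.concatenate(phi)
        rho = np.corrcoef(flat, truth)[0, 1]
        assert abs(rho) > 0.999
        assert mf.var_explained[0] == pytest.approx(1.0, abs=1e-9)
        # scores track the planted loadings up to centering
        assert abs(np.corrcoef(mf.scores[:, 0], s)[0, 1]) > 0.999

    def test_component_unit_norm_and_centered_scores(self, rng):
        curves, _, _, g = planted_curves(rng)
        mf = fpca.mfpca(curves, K=2, grid=g)
        w = mf.weights
        for k in range(2):
            norm = sum((mf.components[k][e] ** 2 * w).sum() for e in range(4))
            assert norm == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(mf.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_identical_subjects_rejected(self, rng):
        curves, *_ = planted_curves(rng, scale=0.0)
        with pytest.raises(ValueError, match="identical"):
            fpca.mfpca(curves, K=2)

    def test_variance_ratio_recovered(self, rng):
        """Two orthogonal planted components with variance ratio 4:1."""
        g = np.linspace(0, 1, 80)
        phi1 = [np.sin(2 * np.pi * g), np.zeros_like(g)]
        phi2 = [np.zeros_like(g), np.sin(2 * np.pi * g)]
        n1 = np.sqrt(sum(np.trapezoid(p**2, g) for p in phi1))
        phi1 = [p / n1 for p in phi1]
        phi2 = [p / n1 for p in phi2]
        n = 50
        # scores with exact sample variances 4 and 1
        s1 = np.linspace(-1, 1, n)
        s1 = s1 / s1.std(ddof=1) * 2.0
        s2 = np.sign(np.arange(n) % 2 - 0.5) * np.ones(n)
        s2 = (s2 - s2.mean()) / s2.std(ddof=1)
        curves = [
            [s1[i] * phi1[e] + s2[i] * phi2[e] for e in range(2)] for i in range(n)
        ]
        mf = fpca.mfpca(curves, K=2, grid=g)
        ratio = mf.var_explained[0] / mf.var_explained[1]
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_common_curve_absorbed_by_mean(self, rng):
        curves, _, _, g = planted_curves(rng)
        shifted = [[c + np.cos(3 * g) for c in subj] for subj in curves]
        a = fpca.mfpca(curves, K=2, grid=g)
        b = fpca.mfpca(shifted, K=2, grid=g)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_reconstruction_residual_matches_var_explained(self, rng):
        g = np.linspace(0, 1, 50)
        x = rng.normal(0, 1, (20, 4, 50))
        curves = [[x[i, e] for e in range(4)] for i in range(20)]
        K = 5
        mf = fpca.mfpca(curves, K=K, grid=g)
        w = np.sqrt(mf.weights)
        resid_var = 0.0
        total_var = 0.0
        for i in range(20):
            for e in range(4):
                recon = mf.mean_functions[e] + sum(
                    mf.scores[i, k] * mf.components[k][e] for k in range(K)
                )
                resid_var += np.sum(((x[i, e] - recon) * w) ** 2)
                total_var += np.sum(((x[i, e] - mf.mean_functions[e]) * w) ** 2)
        frac_unexplained = resid_var / total_var
        assert frac_unexplained == pytest.approx(
            1.0 - mf.var_explained.sum(), abs=0.05
        )

    def test_k_exceeding_subjects_rejected(self, rng):
        curves, *_ = planted_curves(rng, n=3)
        with pytest.raises(ValueError, match="K="):
            fpca.mfpca(curves, K=3)


class TestKruskalWallis:
    def test_hand_ranked_fixture(self):
        # ranks 1,2 | 3,4: H = 12/(4*5) * (2*1 + 2*1) = 2.4
        h, p = fpca.kruskal_wallis(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array(["a", "a", "b", "b"])
        )
        assert h == pytest.approx(2.4)

    def test_all_tied_convention(self):
        h, p = fpca.kruskal_wallis(np.ones(6), np.repeat(["a", "b"], 3))
        assert (h, p) == (0.0, 1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        g = rng.choice(["a", "b", "c"], 30)
        h1, _ = fpca.kruskal_wallis(x, g)
        h2, _ = fpca.kruskal_wallis(np.exp(x), g)
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_large_shift_detected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        g = np.repeat(["a", "b"], 20)
        _, p = fpca.kruskal_wallis(x, g)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fpca.kruskal_wallis(np.arange(3.0), np.array(["a", "a", "a"]))


class TestConoverIman:
    def test_identical_groups_are_null(self):
        out = fpca.conover_iman(np.ones(8), np.repeat(["a", "b"], 4))
        assert out["statistic"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_bh_stepup_fixture(self):
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_shifted_group_has_smallest_adjusted_p(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(4, 1, 15)]
        )
        g = np.repeat(["a", "b", "c"], 15)
        out = fpca.conover_iman(x, g)
        out = out.sort_values("p_adj")
        top_pairs = out.head(2)[["group_a", "group_b"]].to_numpy()
        assert all("c" in pair for pair in top_pairs)
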