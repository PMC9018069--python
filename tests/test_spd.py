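"""Affine-invariant SPD geometry: maps, transport, means, centering."""

import numpy as np
import pytest

from manex import spd
from conftest import random_spd

E = np.e


def scal(x):
    return np.array([[float(x)]])


class TestScalarClosedForms:
    """1x1 SPD matrices reduce every operation to a scalar formula."""

    def test_log_map(self):
        # r * log(s/r): 4 * log(e^2) = 8
        assert spd.log_map(scal(4), scal(4 * E**2)) == pytest.approx(8.0)

    def test_exp_map(self):
        assert spd.exp_map(scal(1), scal(1)) == pytest.approx(E)

    def test_transport(self):
        # G = sqrt(4/1) = 2; G*T*G = 8
        assert spd.transport(scal(1), scal(4), scal(2)) == pytest.approx(8.0)

    def test_distance_is_log_ratio(self):
        assert spd.geodesic_distance(scal(1), scal(E**2)) == pytest.approx(2.0)

    def test_frechet_mean_is_geometric_mean(self):
        m = spd.frechet_mean([scal(1), scal(E**2)])
        assert m[0, 0] == pytest.approx(E, abs=1e-10)

    def test_centering_chain(self):
        # rest=1, grand=4, S=e^2: T=2, Tc=8, Sc=4 e^2
        tcs, cents = spd.center_to_grand_mean(scal(1), [scal(E**2)], scal(4))
        assert tcs[0][0, 0] == pytest.approx(8.0)
        assert cents[0][0, 0] == pytest.approx(4 * E**2)


class TestMaps:
    def test_log_of_reference_is_zero(self, spd_factory):
        a = spd_factory(6)
        assert np.abs(spd.log_map(a, a)).max() < 1e-10

    def test_exp_of_zero_is_reference(self, spd_factory):
        a = spd_factory(6)
        np.testing.assert_allclose(spd.exp_map(a, np.zeros((6, 6))), a, atol=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_roundtrips(self, rng, trial):
        a = random_spd(rng, 10)
        b = random_spd(rng, 10)
        t = spd.log_map(a, b)
        np.testing.assert_allclose(spd.exp_map(a, t), b, atol=1e-8)
        s = rng.standard_normal((10, 10))
        s = 0.5 * (s + s.T)
        np.testing.assert_allclose(spd.log_map(a, spd.exp_map(a, s)), s, atol=1e-8)

    def test_rejects_non_spd(self, rng):
        bad = -np.eye(3)
        with pytest.raises(ValueError, match="positive definite"):
            spd.log_map(np.eye(3), bad)
        with pytest.raises(ValueError, match="symmetric"):
            spd.check_spd(np.triu(np.ones((3, 3))) + np.eye(3))


class TestTransport:
    def test_identity_when_same_reference(self, spd_factory, rng):
        a = spd_factory(5)
        t = rng.standard_normal((5, 5))
        t = t + t.T
        np.testing.assert_allclose(spd.transport(a, a, t), t, atol=1e-10)

    def test_isometry(self, rng):
        """Transport preserves the affine-invariant tangent norm."""
        for _ in range(5):
            a, b = random_spd(rng, 8), random_spd(rng, 8)
            t = rng.standard_normal((8, 8))
            t = t + t.T
            tc = spd.transport(a, b, t)
            na = np.linalg.norm(spd._powm(a, -0.5) @ t @ spd._powm(a, -0.5))
            nb = np.linalg.norm(spd._powm(b, -0.5) @ tc @ spd._powm(b, -0.5))
            assert na == pytest.approx(nb, rel=1e-8)


class TestDistance:
    def test_self_distance_zero(self, spd_factory):
        a = spd_factory(7)
        assert spd.geodesic_distance(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_symmetry(self, rng):
        a, b = random_spd(rng, 6), random_spd(rng, 6)
        assert spd.geodesic_distance(a, b) == pytest.approx(
            spd.geodesic_distance(b, a), rel=1e-10
        )

    def test_congruence_invariance(self, rng):
        a, b = random_spd(rng, 6), random_spd(rng, 6)
        g = rng.standard_normal((6, 6)) + 3 * np.eye(6)  # invertible
        d1 = spd.geodesic_distance(a, b)
        d2 = spd.geodesic_distance(g @ a @ g.T, g @ b @ g.T)
        assert d1 == pytest.approx(d2, rel=1e-8)


class TestFrechetMean:
    def test_single_and_duplicate(self, spd_factory):
        a = spd_factory(5)
        np.testing.assert_allclose(spd.frechet_mean([a]), a)
        np.testing.assert_allclose(spd.frechet_mean([a, a]), a, atol=1e-8)

    def test_scalar_sets_geometric_mean(self, rng):
        vals = rng.uniform(0.1, 10.0, size=7)
        m = spd.frechet_mean([scal(v) for v in vals])
        assert m[0, 0] == pytest.approx(np.exp(np.mean(np.log(vals))), abs=1e-10)

    def test_first_order_condition(self, rng):
        mats = [random_spd(rng, 6) for _ in range(8)]
        m = spd.frechet_mean(mats, tol=1e-10)
        mih = spd._powm(m, -0.5)
        mean_log = np.mean([spd._logm(mih @ r @ mih) for r in mats], axis=0)
        assert np.linalg.norm(mean_log) < 1e-9

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            spd.frechet_mean([])


class TestCentering:
    def test_own_rest_maps_to_grand_mean(self, rng):
        rest, grand = random_spd(rng, 6), random_spd(rng, 6)
        tcs, cents = spd.center_to_grand_mean(rest, [rest], grand)
        assert np.abs(tcs[0]).max() < 1e-8
        np.testing.assert_allclose(cents[0], grand, atol=1e-8)

    def test_identical_relative_shift_gives_identical_tangent(self, rng):
        """Subjects sharing the whitened task shift share the centered vector."""
        grand = random_spd(rng, 5)
        d = rng.standard_normal((5, 5))
        d = 0.2 * (d + d.T)  # common whitened shift, as a log-spectrum
        tangents = []
        for _ in range(2):
            rest = random_spd(rng, 5)
            rh = spd._powm(rest, 0.5)
            task = rh @ spd._expm(d) @ rh  # R^{1/2} e^D R^{1/2}
            tc, _ = spd.center_to_grand_mean(rest, [task], grand)
            tangents.append(tc[0])
        np.testing.assert_allclose(tangents[0], tangents[1], atol=1e-8)

    def test_centering_removes_subject_identity(self, rng):
        """Between-subject distances of shared-task-shift matrices shrink >=10x."""
        grand_pool = []
        tasks, rests = [], []
        d = rng.standard_normal((6, 6))
        d = 0.3 * (d + d.T)
        for _ in range(6):
            rest = random_spd(rng, 6)
            rh = spd._powm(rest, 0.5)
            tasks.append(rh @ spd._expm(d) @ rh)
            rests.append(rest)
        grand = spd.frechet_mean(rests)
        centered = [
            spd.center_to_grand_mean(r, [t], grand)[1][0]
            for r, t in zip(rests, tasks)
        ]

        def mean_pairwise(mats):
            ds = [
                spd.geodesic_distance(mats[i], mats[j])
                for i in range(len(mats))
                for j in range(i + 1, len(mats))
            ]
            return np.mean(ds)

        assert mean_pairwise(tasks) > 10 * mean_pairwise(centered)


class TestShrinkageCovariance:
    def test_spd_when_underdetermined(self, rng):
        x = rng.standard_normal((50, 60))
        s = spd.shrinkage_covariance(x)
        assert np.linalg.eigvalsh(s).min() > 0

    def test_scalar_shrinkage_bounded_by_sample_variance(self):
        s = spd.shrinkage_covariance(np.array([[1.0], [-1.0], [1.0], [-1.0]]))
        assert 0 < s[0, 0] <= 1.0 + 1e-12

    def test_consistency_error_halves_when_n_quadruples(self, rng):
        p = 6
        a = rng.standard_normal((p, p))
        sigma = a @ a.T + p * np.eye(p)
        chol = np.linalg.cholesky(sigma)

        def err(n, reps=20):
            es = []
            for _ in range(reps):
                x = rng.standard_normal((n, p)) @ chol.T
                es.append(np.linalg.norm(spd.shrinkage_covariance(x) - sigma))
            return np.mean(es)

        e1, e2 = err(200), err(800)
        assert e2 < 0.65 * e1  # ~0.5 expected, stochastic slack

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((30, 3))
        x[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            spd.shrinkage_covariance(x)
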