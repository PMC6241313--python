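import numpy as np
import pytest

from diffcentroid.geodesics import MomentaField
from diffcentroid.kernels import KernelConfig, quadratic_form
from diffcentroid.tangent_stats import (
    DegenerateMomentaError,
    approx_distance_matrix,
    centring_ratio,
    direct_distance_matrix,
    extract_momenta,
    kernel_pca,
    matrix_error,
    shoot_mode,
    subject_coordinates,
)
from diffcentroid.testing import identity_kernel

KV = KernelConfig("cauchy", 10.0)


def fields(rng, n_subjects=5, n_points=6, kernel=KV):
    pts = rng.normal(size=(n_points, 3)) * kernel.sigma
    return [
        MomentaField(pts, rng.normal(size=(n_points, 3)), kernel)
        for _ in range(n_subjects)
    ]


class TestCentringRatio:
    def test_symmetric_population_is_zero(self, rng):
        ms = fields(rng, 4)
        pts = ms[0].points
        sym = ms + [MomentaField(pts, -m.alpha, KV) for m in ms]
        assert centring_ratio(sym) == pytest.approx(0.0, abs=1e-12)

    def test_single_nonzero_is_one(self, rng):
        m = fields(rng, 1)
        assert centring_ratio(m) == pytest.approx(1.0)

    def test_duplicated_pair_is_one(self, rng):
        m = fields(rng, 1)[0]
        assert centring_ratio([m, m]) == pytest.approx(1.0)

    def test_all_zero_raises(self):
        m = MomentaField(np.zeros((3, 3)), np.zeros((3, 3)), KV)
        with pytest.raises(DegenerateMomentaError):
            centring_ratio([m, m])

    def test_bounded_by_one(self, rng):
        for _ in range(5):
            assert centring_ratio(fields(rng)) <= 1.0 + 1e-12


class TestKernelPCA:
    def test_identical_momenta_degenerate(self, rng):
        m = fields(rng, 1)[0]
        pca = kernel_pca([m, m, m])
        assert pca.degenerate
        np.testing.assert_allclose(pca.eigenvalues, 0.0, atol=1e-10)

    def test_identity_kernel_matches_plain_pca(self, rng):
        """With K = I the kernel PCA equals standard PCA of stacked coordinates."""
        pts = rng.normal(size=(5, 3))
        fields_ = [
            MomentaField(pts, rng.normal(size=(5, 3)), identity_kernel())
            for _ in range(6)
        ]
        pca = kernel_pca(fields_)
        X = np.stack([m.alpha.ravel() for m in fields_])
        Xc = X - X.mean(axis=0)
        cov_eigs = np.linalg.eigvalsh(Xc @ Xc.T / (len(X) - 1))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, cov_eigs, atol=1e-8)

    def test_cev_non_decreasing_ends_at_one(self, rng):
        pca = kernel_pca(fields(rng, 6))
        assert np.all(np.diff(pca.cev) >= -1e-12)
        assert pca.cev[-1] == pytest.approx(1.0)

    def test_total_variance_trace_identity(self, rng):
        """Sum of eigenvalues equals mean squared K-norm of centred momenta."""
        ms = fields(rng, 6)
        pca = kernel_pca(ms)
        A = np.stack([m.alpha for m in ms])
        Ac = A - A.mean(axis=0)
        pts = ms[0].points
        total = sum(quadratic_form(KV, pts, a, a) for a in Ac) / (len(ms) - 1)
        assert pca.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_inconsistent_points_rejected(self, rng):
        a = fields(rng, 2)
        b = fields(rng, 1)
        with pytest.raises(ValueError):
            kernel_pca(a + b)

    def test_subject_coordinates_reproduce_gram(self, rng):
        ms = fields(rng, 5)
        pca = kernel_pca(ms)
        Z = subject_coordinates(pca)
        # the coordinate Gram matrix reconstructs the centred K_V Gram
        A = np.stack([m.alpha for m in ms])
        Ac = A - A.mean(axis=0)
        pts = ms[0].points
        G = np.array(
            [[quadratic_form(KV, pts, a, b) for b in Ac] for a in Ac]
        ) / (len(ms) - 1)
        np.testing.assert_allclose(Z @ Z.T / (len(ms) - 1), G, atol=1e-8)


class TestShootMode:
    @pytest.fixture
    def pca_and_centre(self, tiny_population):
        pop = tiny_population
        pca = kernel_pca(pop.momenta)
        return pca, pop.base_shape

    def test_zero_amplitude_returns_centre(self, pca_and_centre):
        pca, centre = pca_and_centre
        out = shoot_mode(pca, centre, 0, 0.0)
        np.testing.assert_array_equal(out.vertices, centre.vertices)

    def test_opposite_amplitudes_displace_oppositely(self, pca_and_centre):
        pca, centre = pca_and_centre
        c = 0.1 * np.sqrt(pca.eigenvalues[0])
        plus = shoot_mode(pca, centre, 0, c)
        minus = shoot_mode(pca, centre, 0, -c)
        dp = plus.vertices - centre.vertices
        dm = minus.vertices - centre.vertices
        np.testing.assert_allclose(dp, -dm, rtol=0.05, atol=0.02 * np.abs(dp).max())

    def test_symmetric_w_star_displacement(self, pca_and_centre):
        from diffcentroid.currents import current_sqdist, to_current

        pca, centre = pca_and_centre
        kw = KernelConfig("cauchy", 7.5)
        c = np.sqrt(pca.eigenvalues[0])
        d_plus = current_sqdist(
            to_current(shoot_mode(pca, centre, 0, c)), to_current(centre), kw
        )
        d_minus = current_sqdist(
            to_current(shoot_mode(pca, centre, 0, -c)), to_current(centre), kw
        )
        assert d_plus == pytest.approx(d_minus, rel=0.25)

    def test_degenerate_mode_rejected(self, rng):
        m = fields(rng, 1)[0]
        pca = kernel_pca([m, m, m])
        with pytest.raises(DegenerateMomentaError):
            shoot_mode(pca, None, 0, 0.5)


class TestApproxDistanceMatrix:
    def test_diagonal_zero_and_symmetry(self, rng):
        dm = approx_distance_matrix(fields(rng, 5))
        np.testing.assert_allclose(np.diag(dm.values), 0.0)
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_antipodal_pair_distance(self, rng):
        m = fields(rng, 1)[0]
        neg = MomentaField(m.points, -m.alpha, KV)
        dm = approx_distance_matrix([m, neg])
        assert dm.values[0, 1] == pytest.approx(2 * m.norm(), rel=1e-10)

    def test_matches_elementwise_oracle(self, rng):
        ms = fields(rng, 4)
        dm = approx_distance_matrix(ms)
        pts = ms[0].points
        for i in range(4):
            for j in range(4):
                diff = ms[j].alpha - ms[i].alpha
                expected = np.sqrt(max(quadratic_form(KV, pts, diff, diff), 0))
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-10)


class TestMatrixError:
    def test_identical_matrices_zero(self, rng):
        m = np.abs(rng.normal(size=(4, 4)))
        assert matrix_error(m, m) == 0.0

    def test_two_by_two_hand_computation(self):
        m1 = np.array([[0.0, 1.0], [1.0, 0.0]])
        m2 = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert matrix_error(m1, m2) == pytest.approx(0.25)

    def test_matches_double_loop_oracle(self, rng):
        a = np.abs(rng.normal(size=(5, 5)))
        b = np.abs(rng.normal(size=(5, 5)))
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        total = 0.0
        for i in range(5):
            for j in range(5):
                mx = max(a[i, j], b[i, j])
                if mx > 0:
                    total += abs(a[i, j] - b[i, j]) / mx
        assert matrix_error(a, b) == pytest.approx(total / 25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matrix_error(np.zeros((2, 2)), np.zeros((3, 3)))


class TestExtractMomenta:
    def test_subject_equal_to_centre_gives_zero(self, tiny_population, small_match_cfg):
        pop = tiny_population
        momenta = extract_momenta(pop.base_shape, [pop.base_shape], small_match_cfg)
        assert momenta[0].norm() < 0.05 * small_match_cfg.kernel_V.sigma

    def test_momenta_norm_equals_matching_energy(self, tiny_population, small_match_cfg):
        from diffcentroid.matching import match

        pop = tiny_population
        subject = pop.shapes[0]
        momenta = extract_momenta(pop.base_shape, [subject], small_match_cfg)
        res = match(pop.base_shape, subject, small_match_cfg)
        assert momenta[0].norm_sq() == pytest.approx(res.energy, rel=1e-6)

    def test_reversal_consistency(self, tiny_population, small_match_cfg):
        """Shooting the reversed momenta from the transported points travels
        back near the source."""
        from diffcentroid.geodesics import shoot, transport_points
        from diffcentroid.matching import match

        pop = tiny_population
        src, tgt = pop.shapes[0], pop.shapes[1]
        res = match(src, tgt, small_match_cfg)
        rev = res.final_momenta()
        back_flow = shoot(
            MomentaField(rev.points, -rev.alpha, small_match_cfg.kernel_V),
            small_match_cfg.n_steps,
        )
        returned = transport_points(back_flow, rev.points, 0.0, 1.0)
        travel = np.linalg.norm(res.flow.traj_x[-1] - src.vertices, axis=1).mean()
        err = np.linalg.norm(returned - src.vertices, axis=1).mean()
        assert err < 0.10 * travel


class TestPointReconciliation:
    def test_interpolated_momenta_preserve_velocity_field(self, rng):
        """Momenta moved onto a shared point set reproduce the original
        initial velocity field at those points."""
        from diffcentroid.kernels import convolve
        from diffcentroid.tangent_stats import _reconcile_points

        pts_a = rng.normal(size=(8, 3)) * KV.sigma
        pts_b = pts_a + 0.05 * KV.sigma * rng.normal(size=(8, 3))
        m_a = MomentaField(pts_a, rng.normal(size=(8, 3)), KV)
        m_b = MomentaField(pts_b, rng.normal(size=(8, 3)), KV)
        rec_a, rec_b = _reconcile_points([m_a, m_b], KV)
        np.testing.assert_array_equal(rec_a.points, pts_a)
        np.testing.assert_array_equal(rec_b.points, pts_a)
        v_orig = convolve(KV, pts_a, pts_b, m_b.alpha)
        v_rec = convolve(KV, pts_a, pts_a, rec_b.alpha)
        np.testing.assert_allclose(v_rec, v_orig, rtol=1e-6, atol=1e-8)

    def test_template_momenta_share_points(self, tiny_population, small_match_cfg):
        from diffcentroid.template import variational_template

        shapes = tiny_population.shapes[:2]
        tpl = variational_template(shapes, small_match_cfg, n_outer=1)
        momenta = extract_momenta(tpl, shapes, small_match_cfg)
        assert momenta[0].points.shape == momenta[1].points.shape
        np.testing.assert_array_equal(momenta[0].points, momenta[1].points)


class TestDirectDistanceMatrix:
    def test_duplicate_shapes_near_zero(self, tiny_population, small_match_cfg):
        pop = tiny_population
        shapes = [pop.shapes[0], pop.shapes[0], pop.shapes[1]]
        dm = direct_distance_matrix(shapes, small_match_cfg)
        med = np.median(dm.values[dm.values > 0])
        assert dm.values[0, 1] < 0.05 * med
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_ground_truth_pair_distance(self, tiny_population, small_match_cfg):
        pop = tiny_population
        # distance between antipodal subjects i and i + N/2 is 2 ||alpha_i||_K
        i = 0
        j = i + len(pop.shapes) // 2
        dm = direct_distance_matrix([pop.shapes[i], pop.shapes[j]], small_match_cfg)
        expected = 2 * pop.momenta[i].norm()
        assert dm.values[0, 1] == pytest.approx(expected, rel=0.15)
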