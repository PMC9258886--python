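"""Morphoelastic kinematics and the neo-Hookean stress/energy pair."""

import numpy as np
import pytest

from cortexfold.constitutive import (DegenerateGrowthError, cauchy_stress,
                                     elastic_decomposition, first_pk_stress,
                                     growth_tensor, material_tangent,
                                     strain_energy)

MU, LAME = 1.0, 9.3


def random_states(rng, n):
    """Random well-conditioned (F, Fg) pairs."""
    for _ in range(n):
        F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.3:
            F += np.eye(3)
        N = rng.standard_normal(3)
        N /= np.linalg.norm(N)
        c = rng.uniform(0, 2e-5)
        Fg = growth_tensor(c, 2.0e5, 0.5e5, N)
        yield F, Fg


class TestGrowthTensor:
    def test_identity_at_zero_density(self):
        np.testing.assert_allclose(
            growth_tensor(0.0, 2e5, 2e5, [1, 0, 0]), np.eye(3))

    def test_calibrated_axial_growth(self):
        # c = 1e-5 with the calibrated k_s and no tangential growth
        Fg = growth_tensor(1e-5, 202950.0, 0.0, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(Fg, np.diag([3.0295, 1.0, 1.0]),
                                   rtol=1e-12)

    def test_determinant_eigenstructure(self, rng):
        for _ in range(20):
            N = rng.standard_normal(3)
            N /= np.linalg.norm(N)
            c, kp, kt = rng.uniform(0, 1e-4), 1e5, 3e4
            Fg = growth_tensor(c, kp, kt, N)
            det_expected = (1 + kp * c) * (1 + kt * c) ** 2
            assert np.linalg.det(Fg) == pytest.approx(det_expected,
                                                      rel=1e-12)
            # N is an eigenvector with eigenvalue 1 + kp c
            np.testing.assert_allclose(Fg @ N, (1 + kp * c) * N, rtol=1e-12)

    def test_commutes_with_rotations_about_fiber(self, rng):
        N = np.array([0.0, 0.0, 1.0])
        Fg = growth_tensor(3e-5, 2e5, 1e5, N)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        np.testing.assert_allclose(R @ Fg, Fg @ R, atol=1e-12)

    def test_degenerate_growth_rejected(self):
        with pytest.raises(DegenerateGrowthError):
            growth_tensor(1.0, -2.0, 0.0, [1, 0, 0])

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(ValueError):
            growth_tensor(1e-5, 1e5, 0.0, [2.0, 0.0, 0.0])


class TestElasticDecomposition:
    def test_relaxed_when_F_equals_Fg(self):
        Fg = growth_tensor(2e-5, 2e5, 1e5, [0, 1, 0])
        st = elastic_decomposition(Fg, Fg)
        np.testing.assert_allclose(st.Fe, np.eye(3), atol=1e-12)
        assert st.Je == pytest.approx(1.0)

    def test_constrained_growth(self):
        st = elastic_decomposition(np.eye(3), np.diag([2.0, 1.0, 1.0]))
        np.testing.assert_allclose(st.Fe, np.diag([0.5, 1, 1]))
        assert st.Je == pytest.approx(0.5)

    def test_multiplicative_determinants(self, rng):
        for F, Fg in random_states(rng, 25):
            st = elastic_decomposition(F, Fg)
            assert st.J == pytest.approx(st.Je * st.Jg, rel=1e-12)


class TestStressEnergyConsistency:
    def test_zero_energy_and_stress_at_reference(self):
        assert strain_energy(np.eye(3), 1.0, MU, LAME) == 0.0
        np.testing.assert_allclose(cauchy_stress(np.eye(3), MU, LAME),
                                   np.zeros((3, 3)), atol=1e-14)

    def test_isochoric_energy(self):
        lam = 1.3
        Ce = np.diag([lam ** 2, 1 / lam, 1 / lam])
        expected = 0.5 * MU * (np.trace(Ce) - 3)
        assert strain_energy(Ce, 1.0, MU, LAME) == pytest.approx(expected)

    def test_growth_alone_is_stress_free(self, rng):
        for _, Fg in random_states(rng, 10):
            T = cauchy_stress(np.eye(3), MU, LAME)
            np.testing.assert_allclose(T, 0.0, atol=1e-13)
            st = elastic_decomposition(Fg, Fg)
            np.testing.assert_allclose(cauchy_stress(st.Fe, MU, LAME),
                                       0.0, atol=1e-11)

    def test_stress_matches_energy_gradient(self, rng):
        """Cauchy stress vs central finite differences of the energy
        (100 random elastic states, 1e-5 kPa tolerance)."""
        h = 1e-6
        for k in range(100):
            Fe = np.eye(3) + 0.25 * rng.standard_normal((3, 3))
            if np.linalg.det(Fe) < 0.3:
                Fe += 0.7 * np.eye(3)
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = Fe.copy(), Fe.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    wp = strain_energy(Fp.T @ Fp, np.linalg.det(Fp), MU, LAME)
                    wm = strain_energy(Fm.T @ Fm, np.linalg.det(Fm), MU, LAME)
                    P_fd[i, j] = (wp - wm) / (2 * h)
            # push forward to Cauchy: T = P Fe^T / Je
            T_fd = P_fd @ Fe.T / np.linalg.det(Fe)
            T = cauchy_stress(Fe, MU, LAME)
            np.testing.assert_allclose(T, T_fd, atol=1e-5)
            assert np.allclose(T, T.T, atol=1e-12)

    def test_small_strain_linearization(self):
        """T -> L tr(eps) 1 + 2 mu eps as eps -> 0."""
        rng = np.random.default_rng(7)
        H = rng.standard_normal((3, 3))
        eps_t = 1e-6 * 0.5 * (H + H.T)
        T = cauchy_stress(np.eye(3) + eps_t, MU, LAME)
        T_lin = LAME * np.trace(eps_t) * np.eye(3) + 2 * MU * eps_t
        # agreement to second order: residual ~ (mu + L) |eps|^2
        np.testing.assert_allclose(T, T_lin, atol=5e-11)

    def test_first_pk_consistent_with_cauchy(self, rng):
        for F, Fg in random_states(rng, 15):
            P = first_pk_stress(F, Fg, MU, LAME)
            st = elastic_decomposition(F, Fg)
            T = cauchy_stress(st.Fe, MU, LAME)
            np.testing.assert_allclose(P @ F.T / st.J, T, rtol=1e-9,
                                       atol=1e-12)

    def test_material_tangent_matches_fd(self, rng):
        h = 1e-6
        F, Fg = next(random_states(rng, 1))
        A = material_tangent(F, Fg, MU, LAME)
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                dP = (first_pk_stress(Fp, Fg, MU, LAME)
                      - first_pk_stress(Fm, Fg, MU, LAME)) / (2 * h)
                np.testing.assert_allclose(A[:, :, i, j], dP, atol=5e-5)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(ValueError):
            cauchy_stress(np.diag([-1.0, 1.0, 1.0]), MU, LAME)
        with pytest.raises(ValueError):
            strain_energy(np.eye(3), -0.5, MU, LAME)
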