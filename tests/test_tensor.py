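"""Forward-model physics: tensor symmetry, Euler rotation, twist average."""

import numpy as np
import pytest

from vsfgorient.tensor import (
    POLARIZATIONS,
    GroupedBeta,
    HyperpolarizabilityC7,
    Orientation,
    SusceptibilitySet,
    euler_matrix,
    expand_c7,
    grouped_beta,
    grouped_susceptibilities,
    lab_susceptibilities,
    lab_susceptibilities_quadrature,
)

GENERIC = HyperpolarizabilityC7(
    beta_zzz=1.0, beta_xxz=0.7, beta_xzx=0.55, beta_zxx=0.4,
    beta_xzy=0.3, beta_zxy=0.2, beta_xyz=0.15,
)


def random_beta(rng):
    return HyperpolarizabilityC7.from_array(rng.uniform(-1, 1, 7))


class TestExpandC7:
    def test_zero_beta_gives_zero_tensor(self):
        assert np.all(expand_c7(HyperpolarizabilityC7()) == 0)

    def test_single_component_lands_on_zzz(self):
        B = expand_c7(HyperpolarizabilityC7(beta_zzz=1.0))
        expected = np.zeros((3, 3, 3))
        expected[2, 2, 2] = 1.0
        assert np.array_equal(B, expected)

    def test_generic_beta_has_13_nonzeros_in_7_classes(self):
        B = expand_c7(GENERIC)
        nz = np.abs(B) > 1e-12
        assert nz.sum() == 13
        assert len(np.unique(np.round(np.abs(B[nz]), 12))) == 7

    def test_degeneracy_pattern(self):
        B = expand_c7(GENERIC)
        x, y, z = 0, 1, 2
        assert B[x, x, z] == B[y, y, z]
        assert B[x, z, x] == B[y, z, y]
        assert B[z, x, x] == B[z, y, y]
        assert B[x, z, y] == -B[y, z, x]
        assert B[z, x, y] == -B[z, y, x]
        assert B[x, y, z] == -B[y, x, z]

    def test_nonfinite_component_rejected(self):
        with pytest.raises(ValueError, match="beta_xzx"):
            HyperpolarizabilityC7(beta_xzx=np.nan)


class TestEulerMatrix:
    def test_identity_at_zero_angles(self):
        assert np.allclose(euler_matrix((0.0, 0.0), 0.0), np.eye(3))

    def test_pure_z_rotation(self):
        R = euler_matrix((np.pi / 2, 0.0), 0.0)
        expected = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(R, expected, atol=1e-15)

    def test_proper_rotation(self):
        R = euler_matrix((0.6, 0.4), 1.1)
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-12
        assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_composition_order_z_then_yprime_then_zsecond(self):
        # intrinsic z-y'-z'' equals extrinsic Rz(phi) Ry(theta) Rz(psi)
        phi, theta, psi = 0.3, 0.8, -0.5
        Rz = euler_matrix((phi, 0.0), 0.0)
        Ry = euler_matrix((0.0, theta), 0.0)
        Rz2 = euler_matrix((psi, 0.0), 0.0)
        assert np.allclose(euler_matrix((phi, theta), psi), Rz @ Ry @ Rz2)


class TestLabSusceptibilities:
    def test_zero_tilt_annihilates_all_channels(self, rng):
        for _ in range(50):
            chi = lab_susceptibilities(random_beta(rng), rng.uniform(0, 2 * np.pi), 0.0)
            assert np.abs(chi.to_array()).max() == 0.0

    def test_zero_beta_gives_zero(self):
        chi = lab_susceptibilities(HyperpolarizabilityC7(), 0.3, 0.9)
        assert np.all(chi.to_array() == 0)

    def test_matches_bruteforce_quadrature(self, rng):
        worst = 0.0
        for _ in range(100):
            beta = random_beta(rng)
            phi, theta = rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi)
            closed = lab_susceptibilities(beta, phi, theta).to_array()
            brute = lab_susceptibilities_quadrature(beta, phi, theta, n_psi=720)
            scale = max(np.abs(brute).max(), 1e-30)
            worst = max(worst, np.abs(closed - brute).max() / scale)
        assert worst < 1e-8

    def test_linear_homogeneity_in_beta(self, rng):
        beta = random_beta(rng)
        arr = beta.to_array()
        phi, theta = 0.7, 0.4
        base = lab_susceptibilities(beta, phi, theta).to_array()
        for c in (-1.0, 0.5, 3.0):
            scaled = lab_susceptibilities(
                HyperpolarizabilityC7.from_array(c * arr), phi, theta
            ).to_array()
            assert np.allclose(scaled, c * base, atol=1e-14)

    def test_in_plane_equivariance(self, rng):
        """chi(phi+d) is the rank-3 in-plane rotation of chi(phi)."""
        beta = random_beta(rng)
        theta = 0.9
        phi, d = 0.5, rng.uniform(0, 2 * np.pi)

        def as_tensor(values):
            T = np.zeros((2, 2, 2))
            lab = {"S": 0, "P": 1}
            for p, v in zip(POLARIZATIONS, values):
                T[lab[p[0]], lab[p[1]], lab[p[2]]] = v
            return T

        chi0 = as_tensor(lab_susceptibilities(beta, phi, theta).to_array())
        chi1 = as_tensor(lab_susceptibilities(beta, phi + d, theta).to_array())
        c, s = np.cos(d), np.sin(d)
        Q = np.array([[c, -s], [s, c]])
        rotated = np.einsum("Ii,Jj,Kk,ijk->IJK", Q, Q, Q, chi0)
        assert np.allclose(chi1, rotated, atol=1e-12)


class TestGroupedBeta:
    def test_rank_of_beta_dependence_is_six(self, rng):
        rows = []
        for _ in range(50):
            phi, theta = rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi)
            M = np.column_stack(
                [
                    lab_susceptibilities(
                        HyperpolarizabilityC7.from_array(e), phi, theta
                    ).to_array()
                    for e in np.eye(7)
                ]
            )
            rows.append(M)
        s = np.linalg.svd(np.vstack(rows), compute_uv=False)
        assert (s > 1e-8 * s[0]).sum() == 6

    def test_null_space_direction_is_invisible(self, rng):
        """Perturbing along beta_xzy - beta_zxy - beta_xyz changes nothing."""
        base = random_beta(rng).to_array()
        null = np.array([0, 0, 0, 0, 1.0, -1.0, -1.0])
        other = base + 0.7 * null
        for _ in range(20):
            phi, theta = rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi)
            a = lab_susceptibilities(HyperpolarizabilityC7.from_array(base), phi, theta)
            b = lab_susceptibilities(HyperpolarizabilityC7.from_array(other), phi, theta)
            assert np.abs(a.to_array() - b.to_array()).max() < 1e-10

    def test_equal_grouped_values_give_identical_susceptibilities(self, rng):
        b1 = random_beta(rng)
        g1 = grouped_beta(b1)
        assert isinstance(g1, GroupedBeta)
        # same grouped values, different raw components
        arr = b1.to_array().copy()
        arr[4] += 0.3  # xzy
        arr[5] -= 0.3  # zxy: keeps g5; changes g6 -> compensate via xyz
        arr[6] -= 0.3
        b2 = HyperpolarizabilityC7.from_array(arr)
        assert np.allclose(g1.to_array(), grouped_beta(b2).to_array())
        phi, theta = 1.1, 0.6
        assert np.allclose(
            lab_susceptibilities(b1, phi, theta).to_array(),
            lab_susceptibilities(b2, phi, theta).to_array(),
        )

    def test_theta_zero_dependence_rank_zero(self, rng):
        M = np.column_stack(
            [
                lab_susceptibilities(
                    HyperpolarizabilityC7.from_array(e), rng.uniform(0, 2 * np.pi), 0.0
                ).to_array()
                for e in np.eye(7)
            ]
        )
        assert np.all(M == 0)


class TestTiltDegeneracy:
    def test_compensated_amplitudes_reproduce_susceptibilities(self, rng):
        """Tilt is exactly absorbable into a rescaling of the amplitudes."""
        from vsfgorient.tensor import tilt_compensated_beta

        for _ in range(25):
            g = rng.uniform(-1, 1, 6)
            t1 = rng.uniform(0.1, np.pi / 2 - 0.1)
            t2 = rng.uniform(0.1, np.pi / 2 - 0.1)
            g2 = tilt_compensated_beta(g, t1, t2)
            for phi in rng.uniform(0, 2 * np.pi, 5):
                chi1 = grouped_susceptibilities(g, phi, t1)
                chi2 = grouped_susceptibilities(g2, phi, t2)
                assert np.abs(chi1 - chi2).max() < 1e-12

    def test_degenerate_tilts_rejected(self):
        from vsfgorient.tensor import tilt_compensated_beta

        with pytest.raises(ValueError):
            tilt_compensated_beta(np.ones(6), 0.0, 0.4)


class TestContainers:
    def test_orientation_canonical_domains(self):
        o = Orientation(phi=-0.5, theta=1.0)
        assert 0 <= o.phi < 2 * np.pi
        assert np.isclose(o.phi, 2 * np.pi - 0.5)

    def test_susceptibility_csv_json_round_trip(self, tmp_path):
        chi = lab_susceptibilities(GENERIC, 0.8, 0.5, sheet_id="s1")
        p = tmp_path / "chi.csv"
        chi.to_csv(p)
        back = SusceptibilitySet.from_csv(p)
        assert back.sheet_id == "s1"
        assert np.allclose(back.to_array(), chi.to_array())
        payload = chi.to_json()
        assert "SSP" in payload

    def test_polarization_order_fixed(self):
        assert POLARIZATIONS == ("SSS", "SSP", "SPS", "PSS", "SPP", "PSP", "PPS", "PPP")
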