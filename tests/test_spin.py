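"""Spin operators, tensors, rotations and interaction components."""

import numpy as np
import pytest
from scipy.linalg import eigh

from overtone_sim.constants import GAMMA
from overtone_sim.spin import (CSA, Dipole, Quadrupole, SphericalTensorSet,
                               SpinSystem, commutation_superop,
                               csa_pas_components, dipolar_constant,
                               irreducible_tensors, quad_pas_components,
                               rotate_components, spin_operators,
                               spin_rotation, wigner_d2, wigner_d2_axis)


class TestSpinOperators:
    def test_sz_eigenvalues_spin_half(self):
        ops = spin_operators(0.5)
        assert np.allclose(np.sort(np.diag(ops["z"]).real), [-0.5, 0.5])

    @pytest.mark.parametrize("s", [0.5, 1.0])
    def test_commutation_relations(self, s):
        ops = spin_operators(s)
        for a, b, c in [("x", "y", "z"), ("y", "z", "x"), ("z", "x", "y")]:
            comm = ops[a] @ ops[b] - ops[b] @ ops[a]
            assert np.allclose(comm, 1j * ops[c], atol=1e-12)

    def test_ladder_coefficient(self):
        # S+ |1,-1> = sqrt(2) |1,0>
        ops = spin_operators(1.0)
        v = np.zeros(3)
        v[2] = 1.0
        out = ops["p"] @ v
        expect = np.zeros(3)
        expect[1] = np.sqrt(2.0)
        assert np.allclose(out, expect)

    def test_unsupported_spin_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            spin_operators(1.5)


class TestIrreducibleTensors:
    def test_t20_proportional_to_quadrupole_operator(self):
        t2 = irreducible_tensors(1.0, 2)
        ops = spin_operators(1.0)
        ref = 3 * ops["z"] @ ops["z"] - 2 * np.eye(3)
        assert np.allclose(t2[2], ref / np.sqrt(6))

    def test_identity_rotation_fixes_tensors(self):
        t2 = irreducible_tensors(1.0, 2)
        d = spin_rotation(1.0, (0, 0, 0))
        for t in t2:
            assert np.allclose(d @ t @ d.conj().T, t)

    @pytest.mark.parametrize("k", range(-2, 3))
    def test_z_commutator_counts_coherence_order(self, k):
        t2 = irreducible_tensors(1.0, 2)
        sz = spin_operators(1.0)["z"]
        comm = sz @ t2[k + 2] - t2[k + 2] @ sz
        assert np.allclose(comm, k * t2[k + 2], atol=1e-12)

    def test_rank_exceeding_2s_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            irreducible_tensors(0.5, 2)

    def test_rotation_transforms_with_rank_two(self, rng):
        t2 = irreducible_tensors(1.0, 2)
        eul = tuple(rng.uniform(0, 2 * np.pi, 3))
        d_op = spin_rotation(1.0, eul)
        d2 = wigner_d2(eul)
        for k in range(-2, 3):
            lhs = d_op @ t2[k + 2] @ d_op.conj().T
            rhs = sum(d2[kp + 2, k + 2] * t2[kp + 2] for kp in range(-2, 3))
            assert np.allclose(lhs, rhs, atol=1e-12)


class TestQuadrupole:
    def test_axial_tensor_has_no_pm2_components(self):
        a = quad_pas_components(1e6, 0.0)
        assert a.components[0] == 0 and a.components[4] == 0

    def test_glycine_values_give_hermitian_term(self):
        a = quad_pas_components(1.18e6, 0.53)
        assert a.is_hermitian()
        t2 = irreducible_tensors(1.0, 2)
        h = sum(a.components[k + 2] * t2[k + 2] for k in range(-2, 3))
        assert np.allclose(h, h.conj().T)

    def test_first_order_splitting_is_three_halves_cq(self):
        """Static, eta=0, PAS || B0: SQ line splitting equals 1.5 C_Q."""
        cq = 1.37e6
        a = quad_pas_components(cq, 0.0)
        t2 = irreducible_tensors(1.0, 2)
        ops = spin_operators(1.0)
        h = 2 * np.pi * 25e6 * ops["z"] + sum(
            a.components[k + 2] * t2[k + 2] for k in range(-2, 3))
        w, v = eigh(h)
        mz = np.real(np.einsum("ai,ab,bi->i", v.conj(), ops["z"], v))
        e = {int(round(m)): w[i] for i, m in enumerate(mz)}
        split = ((e[1] - e[0]) - (e[0] - e[-1])) / (2 * np.pi)
        assert abs(split / cq - 1.5) < 1e-6

    def test_eta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quad_pas_components(1e6, 1.2)


class TestCSA:
    def test_zero_anisotropy_gives_zero_components(self):
        a, iso = csa_pas_components(10.0, 0.0, 0.0, 2 * np.pi * 43e6)
        assert np.allclose(a.components, 0)
        assert iso != 0

    def test_nav_parameters_accepted(self):
        a, iso = csa_pas_components(121.0, 105.0, 0.23, 2 * np.pi * 43.37e6)
        assert a.is_hermitian()
        # zeta = 2/3 * delta_sigma
        assert np.isclose(abs(a.components[2]),
                          np.sqrt(1.5) * 2 * np.pi * 43.37e6
                          * (2 / 3) * 105e-6)

    def test_components_linear_in_larmor_frequency(self):
        a1, i1 = csa_pas_components(121.0, 105.0, 0.23, 1e8)
        a2, i2 = csa_pas_components(121.0, 105.0, 0.23, 2e8)
        assert np.allclose(a2.components, 2 * a1.components)
        assert np.isclose(i2, 2 * i1)


class TestDipolarConstant:
    def test_inverse_cube_law(self):
        b1 = dipolar_constant(1.0, GAMMA["1H"], GAMMA["14N"])
        b2 = dipolar_constant(2.0, GAMMA["1H"], GAMMA["14N"])
        assert np.isclose(b1 / b2, 8.0)

    def test_nh_at_106_pm(self):
        # direct evaluation with CODATA gammas: -7290 Hz (frozen)
        b = dipolar_constant(1.06, GAMMA["1H"], GAMMA["14N"])
        assert abs(b - (-7290.3)) < 1.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_constant(0.0, GAMMA["1H"], GAMMA["14N"])


class TestWigner:
    def test_identity(self):
        assert np.allclose(wigner_d2((0, 0, 0)), np.eye(5))

    def test_unitarity_random(self, rng):
        for _ in range(20):
            d = wigner_d2(tuple(rng.uniform(0, 2 * np.pi, 3)))
            assert np.allclose(d @ d.conj().T, np.eye(5), atol=1e-12)

    def test_axis_z_closed_form(self):
        phi = 0.7312
        d = wigner_d2_axis([0, 0, 1], phi)
        expect = np.diag(np.exp(-1j * np.arange(-2, 3) * phi))
        assert np.allclose(d, expect, atol=1e-12)

    def test_axis_and_euler_agree(self, rng):
        """Angle-axis and Euler parameterizations give the same rotation."""
        for _ in range(100):
            a, b, g = rng.uniform(0, 2 * np.pi, 3)
            d_euler = wigner_d2((a, 0, g))
            d_axis = (wigner_d2_axis([0, 0, 1], a)
                      @ wigner_d2_axis([0, 0, 1], g))
            assert np.allclose(d_euler, d_axis, atol=1e-11)
        # general: composition of z-y-z axis rotations equals Euler matrix
        a, b, g = 0.3, 1.2, -0.8
        d1 = wigner_d2((a, b, g))
        d2 = (wigner_d2_axis([0, 0, 1], a) @ wigner_d2_axis([0, 1, 0], b)
              @ wigner_d2_axis([0, 0, 1], g))
        assert np.allclose(d1, d2, atol=1e-11)

    def test_composition(self, rng):
        e1 = tuple(rng.uniform(0, np.pi, 3))
        e2 = tuple(rng.uniform(0, np.pi, 3))
        d12 = wigner_d2(e1) @ wigner_d2(e2)
        # composed rotation via spin-1 comparison route
        r12 = spin_rotation(1.0, e1) @ spin_rotation(1.0, e2)
        t2 = irreducible_tensors(1.0, 2)
        for k in range(-2, 3):
            lhs = r12 @ t2[k + 2] @ r12.conj().T
            rhs = sum(d12[kp + 2, k + 2] * t2[kp + 2] for kp in range(-2, 3))
            assert np.allclose(lhs, rhs, atol=1e-11)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            wigner_d2_axis([0, 0, 2], 0.5)


class TestRotateComponents:
    def test_identity_rotation(self):
        a = quad_pas_components(1.18e6, 0.53)
        b = rotate_components(a, (0, 0, 0))
        assert np.allclose(a.components, b.components)

    def test_invariant_preserved(self, rng):
        a = quad_pas_components(1.18e6, 0.53)
        for _ in range(100):
            b = rotate_components(a, tuple(rng.uniform(0, 2 * np.pi, 3)))
            assert np.isclose(b.norm2, a.norm2)
            assert b.is_hermitian()

    def test_axial_tensor_beta_90_redistribution(self):
        """Rotating an axial PAS by beta=pi/2 follows the d^2_{k0} column."""
        a = quad_pas_components(2e6, 0.0)
        b = rotate_components(a, (0, np.pi / 2, 0))
        a0 = a.components[2]
        beta = np.pi / 2
        # analytic reduced Wigner elements d^2_{k0}(beta)
        d_col = np.array([np.sqrt(3 / 8) * np.sin(beta) ** 2,
                          -np.sqrt(3 / 2) * np.sin(beta) * np.cos(beta),
                          0.5 * (3 * np.cos(beta) ** 2 - 1),
                          np.sqrt(3 / 2) * np.sin(beta) * np.cos(beta),
                          np.sqrt(3 / 8) * np.sin(beta) ** 2])
        assert np.allclose(b.components, a0 * d_col, atol=1e-6 * abs(a0))


class TestCommutationSuperop:
    def test_identity_gives_zero(self):
        assert np.allclose(commutation_superop(np.eye(4)), 0)

    def test_action_matches_commutator(self, rng):
        h = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        h = h + h.conj().T
        rho = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        lhs = commutation_superop(h) @ rho.reshape(-1)
        assert np.allclose(lhs.reshape(3, 3), h @ rho - rho @ h)

    def test_eigenvalues_are_pairwise_differences(self, rng):
        h = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        h = h + h.conj().T
        ev = np.linalg.eigvalsh(h)
        diffs = np.sort((ev[:, None] - ev[None, :]).ravel())
        sup_ev = np.sort(np.linalg.eigvals(commutation_superop(h)).real)
        assert np.allclose(sup_ev, diffs, atol=1e-9)

    def test_linearity(self, rng):
        h1 = rng.normal(size=(3, 3)); h1 = h1 + h1.T
        h2 = rng.normal(size=(3, 3)); h2 = h2 + h2.T
        assert np.allclose(commutation_superop(h1 + h2),
                           commutation_superop(h1) + commutation_superop(h2))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            commutation_superop(np.zeros((2, 3)))


class TestSpinSystem:
    def test_two_spin_one_rejected(self):
        with pytest.raises(ValueError, match="exactly one spin-1"):
            SpinSystem(spins=["14N", "2H"], zeeman_hz=[43e6, 92e6])

    def test_quadrupole_on_spin_half_rejected(self):
        with pytest.raises(ValueError):
            SpinSystem(spins=["14N", "1H"], zeeman_hz=[43e6, 600e6],
                       quadrupole={1: Quadrupole(cq_hz=1e6, eta=0.1)})

    def test_dipole_needs_exactly_one_parameterization(self):
        with pytest.raises(ValueError):
            Dipole(0, 1, r_angstrom=1.0, b_hz=1e3)
        with pytest.raises(ValueError):
            Dipole(0, 1)

    def test_dipole_scaling_helper(self, glycine):
        scaled = glycine.system.with_dipole_scaled(0.0)
        assert scaled.dipoles[0].b_hz == 0.0
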