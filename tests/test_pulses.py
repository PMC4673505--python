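"""Finite-pulse engine: effective Hamiltonians, squaring, RF terms."""

import numpy as np
import pytest

from overtone_sim.constants import MAGIC_ANGLE
from overtone_sim.floquet import FloquetSpace, interaction_terms
from overtone_sim.grids import Orientation
from overtone_sim.pulses import (EffectivePulse, RFChannelSpec, apply_pulse,
                                 effective_hamiltonian,
                                 matrix_power_squaring,
                                 one_period_propagator, pulse_propagator,
                                 rf_operator, rf_term)
from overtone_sim.spin import Quadrupole, SpinSystem


@pytest.fixture(scope="module")
def small_fs():
    """Small-Larmor system: ||H|| T << pi, principal log is safe."""
    sys_ = SpinSystem(spins=["14N"], zeeman_hz=[0.4e6],
                      quadrupole={0: Quadrupole(cq_hz=15e3, eta=0.3)})
    return FloquetSpace(sys_, 3, 2 * np.pi * 9e3, Orientation(0.4, 1.0, 1.0))


def ot_spec(nutation=20e3, offset=0.0, phase=0.0):
    return RFChannelSpec.from_nutation(nutation, MAGIC_ANGLE,
                                       offset=offset, phase=phase)


class TestRFTerm:
    def test_zero_amplitude_is_zero(self, small_fs):
        spec = RFChannelSpec(amplitude=0.0, coil_theta=MAGIC_ANGLE)
        assert np.allclose(rf_term(small_fs, spec, 0.0), 0)

    def test_t0_phase0_proportional_to_coil_operator(self, small_fs):
        spec = ot_spec()
        h = rf_term(small_fs, spec, 0.0)
        op = rf_operator(small_fs, spec)
        assert np.allclose(h, spec.amplitude * op)

    def test_oscillates_at_carrier(self, small_fs):
        spec = ot_spec(offset=2 * np.pi * 5e3)
        omega_z = 2 * np.pi * small_fs.system.zeeman_hz[0]
        t = 1.0 / (spec.carrier(omega_z))  # one radian-ish later
        h = rf_term(small_fs, spec, t)
        expect = spec.amplitude * np.cos(spec.carrier(omega_z) * t)
        assert np.isclose(h.max().real / rf_operator(small_fs, spec).max().real,
                          expect, rtol=1e-10)

    def test_rotating_channel_static(self, small_fs):
        spec = RFChannelSpec(amplitude=2 * np.pi * 89.2e3, channel="rotating")
        h0 = rf_term(small_fs, spec, 0.0, spin_index=0)
        h1 = rf_term(small_fs, spec, 1e-6, spin_index=0)
        assert np.allclose(h0, h1)

    def test_nutation_calibration_factor_two(self):
        spec = ot_spec(nutation=55e3)
        # transverse cosine amplitude = 2 * (2 pi nu_1)
        assert np.isclose(spec.amplitude * np.sin(MAGIC_ANGLE),
                          2 * 2 * np.pi * 55e3)


class TestEffectiveHamiltonian:
    def test_time_independent_generator_recovered(self, small_fs):
        """amp = 0: the effective Hamiltonian equals H_F (log of exp).

        A large carrier offset keeps the Zeeman eigenphases away from the
        +-pi branch line (on resonance they sit at +-pi by construction,
        which is why the pipeline powers the one-period propagator instead
        of exponentiating the log).
        """
        spec = RFChannelSpec(amplitude=0.0, coil_theta=MAGIC_ANGLE,
                             offset=2 * np.pi * 0.5e6)
        pulse = effective_hamiltonian(small_fs, spec)
        h_eff = pulse.effective_hamiltonian_matrix()
        assert np.abs(h_eff - small_fs.hamiltonian()).max() < 1e-3  # rad/s

    def test_sixteen_slices_reproduce_fine_reference(self, small_fs,
                                                     glycine):
        # small system: RF period is artificially long (microseconds)
        p16 = one_period_propagator(small_fs, ot_spec(), n_slices=16)
        p256 = one_period_propagator(small_fs, ot_spec(), n_slices=256)
        assert np.abs(p16.u_period - p256.u_period).max() < 5e-4
        # overtone scale: the 11.5 ns period is quadrature-converged
        from overtone_sim.grids import Orientation
        fs = FloquetSpace(glycine.system, 2, 2 * np.pi * 19.84e3,
                          Orientation(0.8, 1.1, 1.0))
        spec = RFChannelSpec.from_nutation(55e3, MAGIC_ANGLE,
                                           offset=2 * np.pi * 47e3)
        q16 = one_period_propagator(fs, spec, n_slices=16)
        q256 = one_period_propagator(fs, spec, n_slices=256)
        assert np.abs(q16.u_period - q256.u_period).max() < 1e-5

    def test_rf_period_at_141_tesla(self, glycine):
        fs = FloquetSpace(glycine.system, 1, 2 * np.pi * 19.84e3,
                          Orientation(0.1, 0.2, 1.0))
        pulse = one_period_propagator(fs, ot_spec())
        # reciprocal of the printed 86.7448 MHz overtone frequency
        assert np.isclose(pulse.period, 1.0 / 86.7448e6, rtol=1e-6)

    def test_branch_guard_raises_on_pi_eigenphase(self):
        u = np.diag([np.exp(1j * np.pi), 1.0])
        pulse = EffectivePulse(period=1e-8, u_period=u, n_slices=16)
        with pytest.raises(ArithmeticError, match="eigenphase"):
            pulse.effective_hamiltonian_matrix()


class TestPulsePropagator:
    def test_duration_one_period(self, small_fs):
        pulse = one_period_propagator(small_fs, ot_spec())
        u, info = pulse_propagator(pulse, pulse.period)
        assert info["n_periods"] == 1
        assert np.allclose(u, pulse.u_period)

    def test_four_periods_equals_direct_product(self, small_fs):
        pulse = one_period_propagator(small_fs, ot_spec())
        u4, _ = pulse_propagator(pulse, 4 * pulse.period)
        direct = np.linalg.matrix_power(pulse.u_period, 4)
        assert np.abs(u4 - direct).max() < 1e-12

    def test_200us_pulse_squaring_count(self, small_fs):
        pulse = one_period_propagator(small_fs, ot_spec())
        # period here is ~1.25 us (small Larmor); use period count directly
        u, info = pulse_propagator(pulse, 160 * pulse.period)
        assert info["squarings"] <= 20
        assert info["rounding_error_s"] <= pulse.period / 2

    def test_squaring_matches_iterated_multiplication(self, rng):
        u = np.linalg.qr(rng.normal(size=(4, 4))
                         + 1j * rng.normal(size=(4, 4)))[0]
        for n in (1, 2, 7, 13):
            p, sq = matrix_power_squaring(u, n)
            direct = np.linalg.matrix_power(u, n)
            assert np.abs(p - direct).max() < 1e-12

    def test_nonpositive_duration_rejected(self, small_fs):
        pulse = one_period_propagator(small_fs, ot_spec())
        with pytest.raises(ValueError):
            pulse_propagator(pulse, 0.0)


class TestApplyPulse:
    def test_identity_leaves_state(self, rng):
        psi = rng.normal(size=6) + 1j * rng.normal(size=6)
        assert np.allclose(apply_pulse(psi, np.eye(6)), psi)

    def test_norm_preserved_and_half_half(self, small_fs, rng):
        pulse = one_period_propagator(small_fs, ot_spec())
        u2, _ = pulse_propagator(pulse, 2 * pulse.period)
        u4, _ = pulse_propagator(pulse, 4 * pulse.period)
        psi = rng.normal(size=u2.shape[0]) + 1j * rng.normal(size=u2.shape[0])
        psi /= np.linalg.norm(psi)
        out = apply_pulse(apply_pulse(psi, u2), u2)
        assert np.isclose(np.linalg.norm(out), 1.0)
        assert np.allclose(out, apply_pulse(psi, u4), atol=1e-12)

    def test_density_conjugation(self, rng):
        u = np.linalg.qr(rng.normal(size=(3, 3))
                         + 1j * rng.normal(size=(3, 3)))[0]
        rho = rng.normal(size=(3, 3))
        assert np.allclose(apply_pulse(rho, u), u @ rho @ u.conj().T)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_pulse(np.zeros(4), np.eye(3))
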