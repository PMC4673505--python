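"""Sequence library: symmetry phases, selection rules, small experiments."""

import numpy as np
import pytest

from overtone_sim.programs import build_program
from overtone_sim.sequences import (RSymmetry, SimSettings, direct_excitation,
                                    equilibrium_state, overtone_detect_op,
                                    presto_ii, r_phase_list, selection_rules,
                                    spin_echo)


def tiny_settings(**over):
    base = dict(mas_hz=19.84e3, rank=3, grid_order=7, lb_hz=500.0,
                rf_nutation_hz=55e3, n_points=33, window_hz=6e3,
                carrier_offset_hz=47e3, n_phase=16)
    base.update(over)
    return SimSettings(**base)


class TestRSymmetry:
    def test_r18_phase_magnitudes(self):
        assert np.isclose(np.degrees(RSymmetry(18, 2, 5).phi_r), 50.0)
        assert np.isclose(np.degrees(RSymmetry(18, 1, 7).phi_r), 70.0)

    def test_phase_list_alternation(self):
        sym = RSymmetry(18, 2, 5)
        block = 0.4
        ph = r_phase_list(sym, 18, block_phase=block)
        for a, b in zip(ph[:-1], ph[1:]):
            assert np.isclose(np.mod(a + b, 2 * np.pi),
                              np.mod(2 * block, 2 * np.pi))

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError):
            RSymmetry(17, 2, 5)
        with pytest.raises(ValueError):
            r_phase_list(RSymmetry(18, 2, 5), 17)

    def test_element_timing(self):
        sym = RSymmetry(18, 2, 5)
        rotor = 1 / 19.84e3
        assert np.isclose(sym.element_duration(rotor) * sym.big_n,
                          sym.n * rotor)


def brute_force_recoupled(big_n, n, nu, m, mu, lam):
    """Independent enumeration over the integer witness Z."""
    for z in range(-8 * big_n, 8 * big_n + 1):
        if (z - lam) % 2 == 0 and 2 * (m * n - mu * nu) == big_n * z:
            return True
    return False


class TestSelectionRules:
    @pytest.mark.parametrize("n,nu", [(2, 5), (1, 7)])
    def test_r18_family_recouples_paper_set(self, n, nu):
        """R18 symmetries keep only {l,m,lambda,mu} = {2,+-2,1,+-1} among
        the space-rank-2 / spin-rank-1 terms."""
        terms = selection_rules(18, n, nu)
        kept = {(t.l, t.m, t.lam, t.mu) for t in terms
                if t.recoupled and t.lam == 1 and t.l == 2 and t.mu != 0}
        assert kept == {(2, 2, 1, -1), (2, -2, 1, 1)} or kept == {
            (2, 2, 1, 1), (2, -2, 1, -1)}
        # no mu = 0 spin-rank-1 terms survive (heteronuclear decoupling)
        assert not any(t.recoupled for t in terms
                       if t.lam == 1 and t.mu == 0 and t.l == 2)

    def test_matches_brute_force_for_all_even_n_up_to_20(self):
        for big_n in range(2, 21, 2):
            for n in (1, 2, 3):
                for nu in range(-big_n // 2, big_n // 2 + 1):
                    for t in selection_rules(big_n, n, nu):
                        assert t.recoupled == brute_force_recoupled(
                            big_n, n, nu, t.m, t.mu, t.lam)

    def test_nu_zero_recouples_m0_mu0_even_lambda(self):
        terms = selection_rules(8, 1, 0)
        t = next(x for x in terms if x.l == 2 and x.m == 0 and x.lam == 2
                 and x.mu == 0)
        assert t.recoupled and t.z_witness == 0

    def test_nu_sign_flip_mirrors_mu(self):
        a = {(t.m, t.mu) for t in selection_rules(18, 2, 5)
             if t.recoupled and t.lam == 1 and t.l == 2}
        b = {(t.m, -t.mu) for t in selection_rules(18, 2, -5)
             if t.recoupled and t.lam == 1 and t.l == 2}
        assert a == b

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError):
            selection_rules(17, 2, 5)


class TestStatesAndOperators:
    def test_equilibrium_weights_follow_gamma(self, glycine):
        rho = equilibrium_state(glycine.system)
        iz = glycine.system.operator(1, "z")
        w_h = np.trace(rho @ iz).real / np.trace(iz @ iz).real
        assert np.isclose(w_h, 267.5221874 / 19.337792, rtol=1e-6)

    def test_detect_op_is_overtone_coherence(self, glycine):
        p = overtone_detect_op(glycine.system)
        sz = glycine.system.operator(0, "z")
        # coherence order two: [Sz, P] = 2 P
        assert np.allclose(sz @ p - p @ sz, 2 * p)


class TestPrograms:
    def test_events_non_overlapping_and_rotor_synchronized(self):
        settings = tiny_settings()
        sym = RSymmetry(18, 2, 5)
        prog = build_program("presto", settings, sym=sym, tau_exc=201.6e-6,
                             t90=360e-6, t180=720e-6, tau1=0.0, tau2=10e-6)
        prog.validate()
        h_events = [e for e in prog.events if e.channel == "1H"]
        rotor = 1.0 / settings.mas_hz
        # N elements fit exactly in n rotor periods
        block = [e for e in h_events if e.start < 300e-6]
        total = sum(e.duration for e in block)
        n_cycles = len(block) / sym.big_n
        assert abs(total - n_cycles * sym.n * rotor) < 1e-12 * total
        assert len(prog.phase_cycle) == 2

    def test_unsynchronized_tau_exc_rejected(self):
        settings = tiny_settings()
        with pytest.raises(ValueError, match="rotor"):
            build_program("presto", settings, sym=RSymmetry(18, 2, 5),
                          tau_exc=150e-6, t90=360e-6, t180=720e-6)

    def test_direct_table(self):
        prog = build_program("direct", tiny_settings(), pulse_width=260e-6)
        assert "14N-overtone" in prog.table()


class TestSmallExperiments:
    def test_zero_pulse_width_gives_negligible_signal(self, glycine):
        """No pulse, no transverse signal (up to the second-order overlap
        of the thermal state with the overtone coherence, ~1e-2 of the
        excited signal in amplitude terms)."""
        settings = tiny_settings()
        empty = direct_excitation(glycine.system, 0.0, settings)
        pulsed = direct_excitation(glycine.system, 260e-6, settings)
        assert (np.abs(empty.amp).max()
                < 0.02 * np.abs(pulsed.amp).max())

    def test_echo_degenerates_to_direct(self, glycine):
        """t180 = tau1 = tau2 = 0 reduces the echo to pulse-acquire."""
        settings = tiny_settings()
        a = direct_excitation(glycine.system, 100e-6, settings)
        b = spin_echo(glycine.system, 100e-6, 0.0, 0.0, 0.0, settings)
        assert np.abs(a.amp - b.amp).max() < 1e-12 * np.abs(a.amp).max()

    def test_negative_delay_rejected(self, glycine):
        with pytest.raises(ValueError):
            spin_echo(glycine.system, 1e-4, 2e-4, -1e-6, 0.0,
                      tiny_settings())

    def test_presto_unsynchronized_rejected(self, glycine):
        with pytest.raises(ValueError, match="integer number of R cycles"):
            presto_ii(glycine.system, RSymmetry(18, 2, 5), 150e-6,
                      360e-6, 720e-6, 0.0, 10e-6, tiny_settings())

    def test_determinism_bit_identical(self, glycine):
        settings = tiny_settings()
        a = direct_excitation(glycine.system, 60e-6, settings)
        b = direct_excitation(glycine.system, 60e-6, settings)
        assert np.array_equal(a.amp, b.amp)


class TestOrientationMaps:
    def test_maps_and_powder_consistency(self, glycine):
        """Per-orientation peak positions average (signal-weighted) to
        within a linewidth of the powder peak position."""
        from overtone_sim.sequences import orientation_maps
        settings = tiny_settings(grid_order=11, n_points=65, lb_hz=800.0)
        rows = orientation_maps(glycine.system, settings, sequence="direct",
                                pulse_width=260e-6)
        assert {"alpha", "beta", "weight", "height",
                "position_hz"} <= set(rows.columns)
        assert np.isclose(rows["weight"].sum(), 1.0)
        spec = direct_excitation(glycine.system, 260e-6, settings)
        i = int(np.argmax(np.abs(spec.amp)))
        powder_pos = spec.freq_hz[i]
        wsum = (rows["weight"] * rows["height"]).sum()
        mean_pos = ((rows["weight"] * rows["height"]
                     * rows["position_hz"]).sum() / wsum)
        assert abs(mean_pos - powder_pos) < 1.5e3

    def test_presto_has_more_dark_orientations(self, glycine):
        """Recoupling transfer lights up fewer orientations than direct
        excitation (jagged intensity distribution)."""
        from overtone_sim.sequences import RSymmetry, orientation_maps
        settings = tiny_settings(grid_order=11, n_points=65, lb_hz=800.0,
                                 n_phase=12)
        direct = orientation_maps(glycine.system, settings,
                                  sequence="direct", pulse_width=260e-6)
        presto = orientation_maps(glycine.system, settings,
                                  sequence="presto",
                                  sym=RSymmetry(18, 2, 5),
                                  tau_exc=201.6e-6, t90=360e-6, t180=720e-6)

        def dark_fraction(rows):
            h = rows["height"].to_numpy()
            return float(np.mean(h < 0.1 * h.max()))

        assert dark_fraction(presto) > dark_fraction(direct)
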