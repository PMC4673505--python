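"""Pulse-sequence library: direct excitation, nutation, overtone spin echo,
PRESTO-II recoupling, and orientation-resolved diagnostics.

All experiments share one structure: per crystallite orientation the pulse
sequence is propagated exactly on the commensurate carrier-rotor lattice
(:mod:`overtone_sim.lattice`) for a set of spinner-phase samples, and the
post-sequence states are handed to the frequency-domain resolvent detector
built on the Floquet embedding (:mod:`overtone_sim.floquet`).  The rotor
(gamma) phase is averaged over the sample ensemble, the two remaining
powder angles over a spherical quadrature grid.

Observables carry an arbitrary overall scaling: only positions, widths and
ratios are physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .constants import GAMMA, MAGIC_ANGLE
from .detect import Spectrum, peak_metrics, powder_average, relaxation_rate
from .floquet import FloquetSpace, InteractionTerms, interaction_terms
from .grids import Orientation, spherical_grid
from .lattice import CarrierLattice, CrystalliteChain, SequenceState
from .pulses import RFChannelSpec
from .spin import SpinSystem

__all__ = [
    "SimSettings",
    "RSymmetry",
    "r_phase_list",
    "SelectionTerm",
    "selection_rules",
    "equilibrium_state",
    "overtone_detect_op",
    "overtone_centerband_offset",
    "resolve_carrier",
    "direct_excitation",
    "nutation_curve",
    "spin_echo",
    "presto_ii",
    "orientation_maps",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimSettings:
    """Numerical settings of one simulation run.

    ``carrier_offset_hz`` is the carrier offset from the overtone reference
    (twice the nitrogen Larmor frequency); when ``None`` the carrier is
    placed on resonance with the +2 spinning sideband by a coarse pre-scan
    and peak pick (two-pass policy).  ``window_hz`` is the full detection
    window width (default: half the spinning frequency).

    ``decouple_acquisition`` emulates the experimental heteronuclear
    decoupling applied while the signal is recorded: the N-H dipolar
    coupling is removed from the *detection-stage* evolution generator
    (ideal decoupling; the pulses themselves always see the full
    Hamiltonian).
    """

    mas_hz: float
    rank: int = 5
    grid_order: int = 29
    lb_hz: float = 300.0
    rf_nutation_hz: float = 55e3
    coil_theta: float = MAGIC_ANGLE
    n_points: int = 256
    window_hz: float | None = None
    carrier_offset_hz: float | None = None
    n_phase: int = 64
    n_alpha: int | None = None
    n_slices: int = 16
    n_harmonics: int = 32
    decouple_acquisition: bool = True
    strict: bool = True

    def window(self) -> float:
        return self.window_hz if self.window_hz is not None else self.mas_hz / 2


# ---------------------------------------------------------------------------
# RN_n^nu symmetry and selection rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RSymmetry:
    """An ``RN_n^nu`` rotor-synchronized recoupling symmetry.

    ``N`` pi-pulse R elements fit exactly in ``n`` rotor periods; the
    R-pulse phase is ``phi_R = pi nu / N``, alternated between ``+phi_R``
    and ``-phi_R`` so that successive pairs form the repeating unit
    ``{180_{+phi} 180_{-phi}}`` with an overall block phase of 0
    (excitation) or 90 degrees (reconversion).
    """

    big_n: int
    n: int
    nu: int

    def __post_init__(self):
        if self.big_n % 2:
            raise ValueError("N must be even")
        if self.n < 1:
            raise ValueError("n must be a positive integer")

    @property
    def phi_r(self) -> float:
        return np.pi * self.nu / self.big_n

    def element_duration(self, rotor_period: float) -> float:
        return self.n * rotor_period / self.big_n

    def cycle_duration(self, rotor_period: float) -> float:
        return self.n * rotor_period


def r_phase_list(sym: RSymmetry, n_elements: int,
                 block_phase: float = 0.0) -> np.ndarray:
    """Leading phases of successive R elements: alternating +-pi*nu/N.

    Phases are wrapped to [0, 2 pi); the sum of any consecutive pair is
    twice the block phase (mod 2 pi).
    """
    if n_elements % 2:
        raise ValueError("the R element count must be even")
    signs = np.where(np.arange(n_elements) % 2 == 0, 1.0, -1.0)
    return np.mod(block_phase + signs * sym.phi_r, 2 * np.pi)


@dataclass(frozen=True)
class SelectionTerm:
    """A ``{l, m, lambda, mu}`` interaction component with its witness.

    ``recoupled`` is True when ``m n - mu nu = (N/2) Z`` has an integer
    solution ``Z`` of the same parity as ``lambda``.
    """

    l: int
    m: int
    lam: int
    mu: int
    recoupled: bool
    z_witness: int | None


def selection_rules(big_n: int, n: int, nu: int, l_max: int = 2,
                    lam_max: int = 2) -> list[SelectionTerm]:
    """First-order selection rules of an RN_n^nu symmetry.

    Exhaustive enumeration over space components |m| <= l <= l_max and
    spin components |mu| <= lambda <= lam_max.
    """
    if big_n % 2:
        raise ValueError("N must be even")
    out = []
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            for lam in range(lam_max + 1):
                for mu in range(-lam, lam + 1):
                    lhs = m * n - mu * nu
                    z, rem = divmod(2 * lhs, big_n)
                    ok = rem == 0 and (z - lam) % 2 == 0
                    out.append(SelectionTerm(l=l, m=m, lam=lam, mu=mu,
                                             recoupled=bool(ok),
                                             z_witness=z if ok else None))
    return out


# ---------------------------------------------------------------------------
# states, detection operators, carrier placement
# ---------------------------------------------------------------------------

def equilibrium_state(system: SpinSystem) -> np.ndarray:
    """High-temperature thermal state, weights proportional to gamma."""
    g0 = abs(GAMMA[system.spins[system.observed]])
    rho = np.zeros((system.dim, system.dim), complex)
    for i, iso in enumerate(system.spins):
        rho += (GAMMA[iso] / g0) * system.operator(i, "z")
    return rho


def overtone_detect_op(system: SpinSystem) -> np.ndarray:
    """Quadrature detection state: the |+1><-1| coherence of the spin-1."""
    i = system.observed
    d = 3
    s_ot = np.zeros((d, d), complex)
    s_ot[0, d - 1] = 1.0  # basis ordered m = +1, 0, -1
    out = np.ones((1, 1), complex)
    for j, dj in enumerate(system.dims):
        out = np.kron(out, s_ot if j == i else np.eye(dj))
    return out


def overtone_centerband_offset(system: SpinSystem,
                               terms: InteractionTerms | None = None,
                               order: int = 17) -> float:
    """Sphere-averaged static overtone frequency offset (Hz).

    The orientation average of the instantaneous overtone transition
    frequency minus twice the Larmor frequency -- the rotation-invariant
    part that survives magic-angle spinning as the centerband position.
    Used only as the starting point of the carrier search.
    """
    terms = terms if terms is not None else interaction_terms(system)
    obs = system.observed
    szn = system.operator(obs, "z")
    acc = 0.0
    from .floquet import fourier_blocks
    for ori in spherical_grid(order):
        h_m = fourier_blocks(terms, ori)
        h = terms.static + sum(h_m[m + 2] for m in range(-2, 3))
        w, v = eigh(h)
        mz = np.real(np.einsum("ai,ab,bi->i", v.conj(), szn, v))
        e_plus = w[mz > 0.5].mean()
        e_minus = w[mz < -0.5].mean()
        acc += ori.weight * (e_plus - e_minus)
    nu_n = abs(system.zeeman_hz[system.observed])
    return acc / (2 * np.pi) - 2 * nu_n


# ---------------------------------------------------------------------------
# powder driver
# ---------------------------------------------------------------------------

def _overtone_op(system: SpinSystem, coil_theta: float) -> np.ndarray:
    i = system.observed
    return (np.sin(coil_theta) * system.operator(i, "x")
            + np.cos(coil_theta) * system.operator(i, "z"))


class _Env:
    """Per-orientation bundle handed to sequence builders."""

    def __init__(self, system, settings, terms, lattice, ori):
        self.system = system
        self.settings = settings
        self.terms = terms
        self.lattice = lattice
        self.orientation = ori
        self.chain = CrystalliteChain(lattice, terms, ori,
                                      n_harmonics=settings.n_harmonics,
                                      n_slices=settings.n_slices)
        self.ot_op = _overtone_op(system, settings.coil_theta)

    def new_state(self) -> SequenceState:
        return SequenceState(self.chain, self.settings.n_phase)

    def ot_pulse(self, state: SequenceState, duration: float,
                 nutation_hz: float, phase: float = 0.0) -> float:
        """Apply an overtone pulse; returns the realized duration."""
        spec = RFChannelSpec.from_nutation(nutation_hz,
                                           self.settings.coil_theta,
                                           phase=phase)
        n = self.lattice.periods(duration)
        ps = self.chain.period_set(("ot", nutation_hz, round(phase, 10)),
                                   cosine_amp=spec.amplitude,
                                   cosine_op=self.ot_op, rf_phase=phase)
        state.apply(ps, n)
        return n * self.lattice.period

    def delay(self, state: SequenceState, duration: float) -> float:
        n = self.lattice.periods(duration)
        ps = self.chain.period_set("free")
        state.apply(ps, n)
        return n * self.lattice.period

    def h_pulse(self, state: SequenceState, n_periods: int,
                nutation_hz: float, phase: float, spin: int) -> None:
        """Rotating-frame pulse on a spin-1/2 channel (exact duration in
        RF periods, supplied by the caller from rotor synchronization)."""
        sys_ = self.system
        op = 2 * np.pi * nutation_hz * (
            np.cos(phase) * sys_.operator(spin, "x")
            + np.sin(phase) * sys_.operator(spin, "y"))
        ps = self.chain.period_set(("h", spin, nutation_hz, round(phase, 10)),
                                   extra_static=op)
        state.apply(ps, n_periods)


def _resolve_offset(system, settings, terms) -> float:
    if settings.carrier_offset_hz is not None:
        return settings.carrier_offset_hz
    return resolve_carrier(system, settings, terms=terms)


def _axis(settings, lattice, omega_z) -> tuple[np.ndarray, np.ndarray]:
    carrier_hz = lattice.carrier_rad / (2 * np.pi) - 2 * abs(omega_z) / (
        2 * np.pi)
    ax = np.linspace(-settings.window() / 2, settings.window() / 2,
                     settings.n_points)
    omega_abs = lattice.carrier_rad + 2 * np.pi * ax
    return ax, omega_abs


def _run_powder(system, settings, build, multiple_of: int = 1,
                collect: bool = False, carrier_offset_hz: float | None = None,
                terms: InteractionTerms | None = None):
    """Run a sequence over the powder grid.

    ``build(env, label_sink)`` must return a dict label -> SequenceState
    (several labels share the per-orientation lattice work, e.g. the
    widths of a nutation sweep or the scans of a phase cycle with signed
    weights: the value may also be a list of (weight, SequenceState)).
    """
    terms = terms if terms is not None else interaction_terms(system)
    omega_z = 2 * np.pi * system.zeeman_hz[system.observed]
    offset = (carrier_offset_hz if carrier_offset_hz is not None
              else _resolve_offset(system, settings, terms))
    lattice = CarrierLattice.commensurate(omega_z, 2 * np.pi * offset,
                                          settings.mas_hz, multiple_of)
    ax, omega_abs = _axis(settings, lattice, omega_z)
    r = relaxation_rate(settings.lb_hz)
    rho0 = equilibrium_state(system)
    p_op = overtone_detect_op(system)
    if settings.decouple_acquisition and system.dipoles:
        system_det = system.with_dipole_scaled(0.0)
        terms_det = interaction_terms(system_det)
    else:
        system_det, terms_det = system, terms
    grid = spherical_grid(settings.grid_order, settings.n_alpha)
    acc: dict = {}
    rows = []
    for ori in grid:
        env = _Env(system, settings, terms, lattice, ori)
        fs = FloquetSpace(system_det, settings.rank, lattice.mas_rad, ori,
                          terms=terms_det)
        out = build(env)
        for label, item in out.items():
            entries = item if isinstance(item, list) else [(1.0, item)]
            amp = np.zeros(len(omega_abs), complex)
            for wgt, seqstate in entries:
                states = seqstate.states(rho0)
                amp = amp + wgt * fs.spectrum_phased(
                    states, seqstate.end_phases(), p_op, omega_abs, r)
            if label not in acc:
                acc[label] = np.zeros(len(omega_abs), complex)
            acc[label] += ori.weight * amp
            if collect:
                mag = np.abs(amp)
                i = int(np.argmax(mag))
                rows.append({"label": label, "alpha": ori.alpha,
                             "beta": ori.beta, "weight": ori.weight,
                             "height": float(mag[i]),
                             "position_hz": float(ax[i])})
    meta_base = {
        "mas_hz": lattice.mas_hz, "mas_requested_hz": settings.mas_hz,
        "carrier_offset_hz": offset,
        "carrier_hz": lattice.carrier_rad / (2 * np.pi),
        "nitrogen_ref_hz": abs(system.zeeman_hz[system.observed]),
        "rank": settings.rank, "grid_order": settings.grid_order,
        "lb_hz": settings.lb_hz, "n_phase": settings.n_phase,
        "n_slices": settings.n_slices, "coil_theta": settings.coil_theta,
    }
    spectra = {lbl: Spectrum(ax, a, dict(meta_base, label=str(lbl)))
               for lbl, a in acc.items()}
    if collect:
        return spectra, pd.DataFrame(rows)
    return spectra


# ---------------------------------------------------------------------------
# carrier placement (two-pass peak pick)
# ---------------------------------------------------------------------------

def resolve_carrier(system: SpinSystem, settings: SimSettings,
                    pulse_width: float = 260e-6,
                    terms: InteractionTerms | None = None,
                    max_iter: int = 4) -> float:
    """Place the carrier on resonance with the +2 spinning sideband.

    Starting from the sphere-averaged centerband position plus twice the
    spinning frequency, a coarse direct-excitation powder spectrum is
    simulated and the carrier is moved to its peak until self-consistent
    (the experimental procedure: optimize on the +2 sideband).  Returns
    the carrier offset from the overtone reference in Hz.
    """
    terms = terms if terms is not None else interaction_terms(system)
    coarse = replace(settings, grid_order=min(settings.grid_order, 17),
                     n_phase=max(16, settings.n_phase // 2), n_alpha=12,
                     n_points=161, window_hz=max(12e3, 6 * settings.lb_hz),
                     carrier_offset_hz=0.0)
    offset = (overtone_centerband_offset(system, terms)
              + 2 * settings.mas_hz)
    step = coarse.window() / (coarse.n_points - 1)
    for _ in range(max_iter):
        def build(env):
            st = env.new_state()
            env.ot_pulse(st, pulse_width, settings.rf_nutation_hz)
            return {"scan": st}

        spec = _run_powder(system, coarse, build,
                           carrier_offset_hz=offset, terms=terms)["scan"]
        i = int(np.argmax(np.abs(spec.amp)))
        shift = spec.freq_hz[i]
        offset += shift
        if abs(shift) <= 2 * step:
            break
    return float(offset)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def direct_excitation(system: SpinSystem, pulse_width: float,
                      settings: SimSettings) -> Spectrum:
    """Pulse-acquire overtone spectrum around the +2 spinning sideband.

    The finite excitation pulse is simulated exactly (never assumed
    ideal); zero pulse width returns zero signal.
    """

    def build(env):
        st = env.new_state()
        if pulse_width > 0:
            env.ot_pulse(st, pulse_width, settings.rf_nutation_hz)
        return {"spec": st}

    spec = _run_powder(system, settings, build)["spec"]
    spec.meta.update(sequence="direct_excitation",
                     pulse_width_s=pulse_width,
                     rf_nutation_hz=settings.rf_nutation_hz)
    return spec


def nutation_curve(system: SpinSystem, widths, settings: SimSettings
                   ) -> pd.DataFrame:
    """Signal amplitude at the +2 sideband versus excitation pulse width.

    Returns a DataFrame with the realized pulse widths, the peak height of
    the sideband (magnitude of the complex spectrum at its maximum) and
    the phased on-resonance amplitude.  Deterministic; the overall scale
    is arbitrary.
    """
    widths = np.asarray(sorted(widths), float)

    def build(env):
        out = {}
        st = env.new_state()
        realized = 0.0
        for wd in widths:
            realized += env.ot_pulse(st, wd - realized,
                                     settings.rf_nutation_hz)
            out[float(wd)] = st.copy()
        return out

    spectra = _run_powder(system, settings, build)
    rows = []
    for wd in widths:
        s = spectra[float(wd)]
        mag = np.abs(s.amp)
        i = int(np.argmax(mag))
        rows.append({"width_s": float(wd), "height": float(mag[i]),
                     "position_hz": float(s.freq_hz[i]),
                     "on_resonance": complex(
                         s.amp[np.argmin(np.abs(s.freq_hz))])})
    return pd.DataFrame(rows)


def spin_echo(system: SpinSystem, t90: float, t180: float, tau1: float,
              tau2: float, settings: SimSettings,
              phase90: float = 0.0, phase180: float = 0.0) -> Spectrum:
    """Overtone spin echo: 90 - tau1 - 180 - tau2 - acquire.

    Both overtone pulses are propagated with the finite-pulse engine; no
    phase correction is applied to the result.  Degenerates to direct
    excitation for ``t180 = tau1 = tau2 = 0``.
    """
    if tau1 < 0 or tau2 < 0:
        raise ValueError("echo delays must be non-negative")

    def build(env):
        st = env.new_state()
        if t90 > 0:
            env.ot_pulse(st, t90, settings.rf_nutation_hz, phase=phase90)
        if tau1 > 0:
            env.delay(st, tau1)
        if t180 > 0:
            env.ot_pulse(st, t180, settings.rf_nutation_hz, phase=phase180)
        if tau2 > 0:
            env.delay(st, tau2)
        return {"spec": st}

    spec = _run_powder(system, settings, build)["spec"]
    spec.meta.update(sequence="spin_echo", t90_s=t90, t180_s=t180,
                     tau1_s=tau1, tau2_s=tau2)
    return spec


def _r_block(env, st, sym: RSymmetry, n_cycles: int, block_phase: float,
             h_spin: int, h_nutation_hz: float | None) -> None:
    """One R-symmetry recoupling block on the proton channel.

    ``N`` R elements per ``n`` rotor periods, each element a simple pi
    pulse of duration ``n tau_r / N`` whose phase alternates between
    ``+phi_R`` and ``-phi_R`` (successive pairs form the repeating unit
    ``{180_{+phi} 180_{-phi}}`` carrying the overall block phase).  The
    proton amplitude follows from rotor synchronization, ``nu_1 = N /
    (2 n tau_r)`` -- 89.3 kHz for R18 in two rotor periods at 19.84 kHz
    spinning -- unless an explicit amplitude is supplied.
    """
    q = env.lattice.q
    n_el = sym.big_n * n_cycles
    if (sym.n * q) % sym.big_n != 0:
        raise ValueError("lattice not divisible into R elements; build the "
                         "lattice with the proper multiple_of")
    per_el = (sym.n * q) // sym.big_n
    if h_nutation_hz is None:
        h_nutation_hz = 1.0 / (2 * per_el * env.lattice.period)
    phases = r_phase_list(sym, n_el, block_phase)
    for e in range(n_el):
        env.h_pulse(st, per_el, h_nutation_hz, phases[e], h_spin)


def presto_ii(system: SpinSystem, sym: RSymmetry, tau_exc: float,
              t90: float, t180: float, tau1: float, tau2: float,
              settings: SimSettings, h_nutation_hz: float | None = None,
              keep_direct: bool = False) -> Spectrum:
    """PRESTO-II polarization transfer from 1H to the 14N overtone.

    Layout: excitation R block (``{180_{+phi}180_{-phi}}_0``) on the
    proton channel, then the overtone spin echo (90 - tau1 - 180), then
    the reconversion R block (``{..}_90``), then ``tau2`` and acquisition.
    Excitation and reconversion durations are equal and must be an integer
    number of R cycles (rotor-synchronized), otherwise rejected.  A
    two-step phase cycle of the excitation block (receiver +/-) removes
    the directly excited overtone signal; ``keep_direct`` disables the
    cycle and retains both pathways.
    """
    h_spin = next(i for i, iso in enumerate(system.spins)
                  if i != system.observed)
    rotor = 1.0 / settings.mas_hz
    n_cycles = tau_exc / sym.cycle_duration(rotor)
    if abs(n_cycles - round(n_cycles)) > 1e-3:
        raise ValueError(
            f"tau_exc = {tau_exc:g} s is not an integer number of R cycles "
            f"(cycle = {sym.cycle_duration(rotor):g} s)")
    n_cycles = int(round(n_cycles))

    def build(env):
        out = []
        cycle_phases = [0.0] if keep_direct else [0.0, np.pi]
        signs = [1.0] if keep_direct else [0.5, -0.5]
        for ph_cyc, sgn in zip(cycle_phases, signs):
            st = env.new_state()
            _r_block(env, st, sym, n_cycles, ph_cyc, h_spin, h_nutation_hz)
            env.ot_pulse(st, t90, settings.rf_nutation_hz)
            if tau1 > 0:
                env.delay(st, tau1)
            env.ot_pulse(st, t180, settings.rf_nutation_hz)
            _r_block(env, st, sym, n_cycles, np.pi / 2, h_spin,
                     h_nutation_hz)
            if tau2 > 0:
                env.delay(st, tau2)
            out.append((sgn, st))
        return {"spec": out}

    multiple = sym.big_n // int(np.gcd(sym.big_n, sym.n))
    spec = _run_powder(system, settings, build, multiple_of=multiple)["spec"]
    spec.meta.update(sequence="presto_ii", symmetry=f"R{sym.big_n}_{sym.n}^"
                     f"{sym.nu}", tau_exc_s=tau_exc, t90_s=t90,
                     t180_s=t180, tau1_s=tau1, tau2_s=tau2,
                     phase_cycled=not keep_direct)
    return spec


def orientation_maps(system: SpinSystem, settings: SimSettings,
                     sequence: str = "direct", **seq_kwargs) -> pd.DataFrame:
    """Per-orientation signal intensity and position distributions.

    Runs the requested sequence ("direct" or "presto") once per powder
    orientation and records the peak height and position of each
    crystallite's contribution; the gamma angle is averaged analytically
    by the detection embedding.
    """
    if sequence == "direct":
        pulse_width = seq_kwargs.get("pulse_width", 260e-6)

        def build(env):
            st = env.new_state()
            env.ot_pulse(st, pulse_width, settings.rf_nutation_hz)
            return {"direct": st}

        _, rows = _run_powder(system, settings, build, collect=True)
        return rows
    if sequence == "presto":
        sym = seq_kwargs["sym"]
        rotor = 1.0 / settings.mas_hz
        n_cycles = int(round(seq_kwargs["tau_exc"]
                             / sym.cycle_duration(rotor)))
        h_spin = next(i for i, iso in enumerate(system.spins)
                      if i != system.observed)

        def build(env):
            out = []
            for ph_cyc, sgn in [(0.0, 0.5), (np.pi, -0.5)]:
                st = env.new_state()
                _r_block(env, st, sym, n_cycles, ph_cyc, h_spin,
                         seq_kwargs.get("h_nutation_hz"))
                env.ot_pulse(st, seq_kwargs["t90"], settings.rf_nutation_hz)
                env.ot_pulse(st, seq_kwargs["t180"], settings.rf_nutation_hz)
                _r_block(env, st, sym, n_cycles, np.pi / 2, h_spin,
                         seq_kwargs.get("h_nutation_hz"))
                out.append((sgn, st))
            return {"presto": out}

        multiple = sym.big_n // int(np.gcd(sym.big_n, sym.n))
        _, rows = _run_powder(system, settings, build, collect=True,
                              multiple_of=multiple)
        return rows
    raise ValueError(f"unknown sequence {sequence!r}")
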