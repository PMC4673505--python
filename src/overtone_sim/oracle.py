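"""Brute-force laboratory-frame time-sliced propagation.

Reference implementation used only as a test oracle: the Hamiltonian is
evaluated at slice midpoints (second-order product integral) with the rotor
phase and the radiofrequency carrier written out explicitly in absolute
time, and the propagator is accumulated slice by slice.  Slow by design --
this is exactly the cost the Floquet / effective-Hamiltonian pipeline
avoids.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh

from .floquet import InteractionTerms, fourier_blocks
from .grids import Orientation

__all__ = ["lab_frame_propagator", "lab_frame_fid"]


def _expm_herm(h: np.ndarray, dt: float) -> np.ndarray:
    w, v = eigh(h)
    return (v * np.exp(-1j * w * dt)) @ v.conj().T


def _check_timestep(dt: float, events, omega_fastest: float) -> None:
    if dt > np.pi / omega_fastest:
        raise ValueError(
            f"timestep {dt:g} s too coarse: need >= 2 points per period of "
            f"the fastest oscillation ({omega_fastest / 2 / np.pi:g} Hz)")


def lab_frame_propagator(terms: InteractionTerms, orientation: Orientation,
                         omega_mas: float, events, dt: float,
                         phi0: float = 0.0, t_start: float = 0.0
                         ) -> np.ndarray:
    """Time-ordered propagator over a list of events.

    Each event is ``(duration, rf)`` where ``rf`` is ``None`` (free
    evolution) or a callable ``rf(t) -> Hamiltonian matrix`` evaluated at
    absolute time.  ``dt`` must resolve the fastest oscillation present
    (two points per period), including the overtone carrier when RF is on.
    """
    h_m = fourier_blocks(terms, orientation)
    static = terms.static
    omega_z = float(np.abs(np.diag(static.real)).max())
    _check_timestep(dt, events, max(2 * omega_z, omega_mas, 1.0))

    dim = terms.dim
    u = np.eye(dim, dtype=complex)
    t = t_start
    for duration, rf in events:
        n_steps = max(1, int(round(duration / dt)))
        step = duration / n_steps
        for k in range(n_steps):
            tm = t + (k + 0.5) * step
            phi = omega_mas * tm + phi0
            h = static.copy()
            for m in (-2, -1, 0, 1, 2):
                h += h_m[m + 2] * np.exp(-1j * m * phi)
            if rf is not None:
                h += rf(tm)
            u = _expm_herm(h, step) @ u
        t += duration
    return u


def lab_frame_fid(terms: InteractionTerms, orientation: Orientation,
                  omega_mas: float, rho0: np.ndarray, detect: np.ndarray,
                  times: np.ndarray, dt: float, phi0: float = 0.0
                  ) -> np.ndarray:
    """Free-evolution FID ``Tr[detect^+ rho(t)]`` on the sampling grid."""
    times = np.asarray(times, float)
    fid = np.zeros(len(times), complex)
    rho = rho0.copy()
    t_prev = 0.0
    for i, t in enumerate(times):
        if t > t_prev:
            u = lab_frame_propagator(terms, orientation, omega_mas,
                                     [(t - t_prev, None)], dt, phi0=phi0,
                                     t_start=t_prev)
            rho = u @ rho @ u.conj().T
            t_prev = t
        fid[i] = np.trace(detect.conj().T @ rho)
    return fid
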