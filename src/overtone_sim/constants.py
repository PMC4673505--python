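"""Physical constants and sign conventions.

Gyromagnetic ratios are CODATA values in rad s^-1 T^-1.  The Larmor
frequencies actually used in simulations are configuration inputs (the
spectrometer reference frequencies), not derived from gamma * B0, because
the exact field calibration of a given magnet is never known to ppm
accuracy; gamma enters only through the dipolar coupling constant.

Sign conventions (fixed once, validated by observable-level oracles):

* The Zeeman Hamiltonian of the observed nucleus is ``+omega_Z * Sz`` with
  ``omega_Z = 2*pi*zeeman_hz`` and ``zeeman_hz > 0`` for 14N.  Only line
  positions and splittings are contractual.
* The dipolar coupling constant is ``b = -(mu0/4pi) * g1*g2*hbar / r^3``
  (negative for two positive-gamma nuclei).
"""

import numpy as np

MU0 = 1.25663706212e-6          # vacuum permeability, N A^-2
HBAR = 1.054571817e-34          # reduced Planck constant, J s

#: gyromagnetic ratios, rad s^-1 T^-1
GAMMA = {
    "1H": 267.5221874e6,
    "2H": 41.065e6,
    "14N": 19.337792e6,
    "15N": -27.126e6,
    "13C": 67.2828e6,
}

#: spin quantum numbers of the supported isotopes
SPIN = {
    "1H": 0.5,
    "2H": 1.0,
    "14N": 1.0,
    "15N": 0.5,
    "13C": 0.5,
}

#: the magic angle, arccos(1/sqrt(3)), radians
MAGIC_ANGLE = float(np.arccos(1.0 / np.sqrt(3.0)))
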