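"""Built-in model systems: glycine and N-acetyl-valine (NAV).

Both are two-spin 14N-1H models.  Glycine's NH3 rotation is represented by
a single N-H dipolar coupling along the rotation axis at an effective
distance of 1.28 A (motional-averaging proxy); NAV carries the full 14N
shielding tensor of the peptide-bond model.  Dipolar and shielding tensor
orientations are quoted relative to the eigenframe of the 14N quadrupole
tensor, which serves as the molecular frame.  Reference overtone
frequencies: 86.7448 MHz at 14.1 T and 122.8331 MHz at 20.0 T
(spectrometer calibration constants, not derived from gamma * B0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import SimSettings
from .spin import CSA, Dipole, Quadrupole, SpinSystem

__all__ = ["OVERTONE_REF_HZ", "FIXTURES", "load_fixture", "FixtureDefaults"]

#: overtone reference frequencies by nominal field (T)
OVERTONE_REF_HZ = {14.1: 86.7448e6, 20.0: 122.8331e6}

DEG = np.pi / 180.0


@dataclass(frozen=True)
class FixtureDefaults:
    """Simulation defaults that accompany a fixture."""

    system: SpinSystem
    rank: int
    grid_order: int
    lb_hz: float
    field_t: float

    def settings(self, mas_hz: float, **overrides) -> SimSettings:
        base = dict(mas_hz=mas_hz, rank=self.rank,
                    grid_order=self.grid_order, lb_hz=self.lb_hz)
        base.update(overrides)
        return SimSettings(**base)


def _proton_larmor(field_t: float) -> float:
    # only the sign/frame matter (the proton is in its rotating frame);
    # the nominal value is recorded for completeness
    return {14.1: 600.13e6, 20.0: 850.0e6}[field_t]


def load_fixture(name: str, field_t: float = 14.1) -> FixtureDefaults:
    """Table of model systems: ``glycine`` or ``NAV``."""
    nu_n = OVERTONE_REF_HZ[field_t] / 2.0
    key = name.lower()
    if key in ("glycine", "gly"):
        system = SpinSystem(
            spins=["14N", "1H"],
            zeeman_hz=[nu_n, _proton_larmor(field_t)],
            quadrupole={0: Quadrupole(cq_hz=1.18e6, eta=0.53)},
            csa={0: CSA(sigma_iso_ppm=32.4)},
            dipoles=[Dipole(0, 1, r_angstrom=1.28, euler=(0.0, 0.0, 0.0))],
        )
        return FixtureDefaults(system=system, rank=5, grid_order=77,
                               lb_hz=300.0, field_t=field_t)
    if key in ("nav", "n-acetyl-valine", "n-acetylvaline"):
        system = SpinSystem(
            spins=["14N", "1H"],
            zeeman_hz=[nu_n, _proton_larmor(field_t)],
            quadrupole={0: Quadrupole(cq_hz=3.21e6, eta=0.32)},
            csa={0: CSA(sigma_iso_ppm=121.0, delta_sigma_ppm=105.0,
                        eta=0.23,
                        euler=(-90 * DEG, -90 * DEG, -17 * DEG))},
            dipoles=[Dipole(0, 1, r_angstrom=1.06,
                            euler=(0.0, 90 * DEG, 0.0))],
        )
        return FixtureDefaults(system=system, rank=5, grid_order=131,
                               lb_hz=2000.0, field_t=field_t)
    raise ValueError(f"unknown fixture {name!r}; available: glycine, NAV")


FIXTURES = ("glycine", "NAV")
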