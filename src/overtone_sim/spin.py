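"""Spin operators, irreducible spherical tensors and interaction tensors.

Conventions
-----------
Euler angles are ZYZ, active:  ``R(alpha, beta, gamma) = Rz(alpha) Ry(beta)
Rz(gamma)``; the corresponding rotation operator on spin states is
``D(Omega) = exp(-i alpha Sz) exp(-i beta Sy) exp(-i gamma Sz)``.  Spherical
tensor operators transform as ``D T_{l,k} D^+ = sum_k' D^l_{k',k}(Omega)
T_{l,k'}`` and spatial components accordingly as ``a'_{k'} = sum_k
D^l_{k',k}(Omega) a_k``.

Rank-2 spin tensors follow

    T_{2,0}   = (3 Sz^2 - S(S+1)) / sqrt(6)
    T_{2,+-1} = -+ (Sz S+- + S+- Sz) / 2
    T_{2,+-2} = S+-^2 / 2

under which the quadrupolar Hamiltonian with PAS components produced by
:func:`quad_pas_components` reproduces the textbook first-order
single-quantum splitting of (3/2) C_Q for an axial tensor aligned with the
field (this oracle, not the internal convention, is the public contract).

Spherical tensor component arrays are indexed ``k = -l .. +l`` (ascending,
so index ``k + l``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .constants import GAMMA, HBAR, MU0, SPIN

__all__ = [
    "spin_operators",
    "irreducible_tensors",
    "pair_tensors",
    "spin_rotation",
    "wigner_d",
    "wigner_d2",
    "wigner_d2_axis",
    "rotate_components",
    "commutation_superop",
    "SphericalTensorSet",
    "quad_pas_components",
    "csa_pas_components",
    "dipolar_constant",
    "Quadrupole",
    "CSA",
    "Dipole",
    "SpinSystem",
]


# ---------------------------------------------------------------------------
# elementary operators
# ---------------------------------------------------------------------------

def spin_operators(S: float) -> dict[str, np.ndarray]:
    """Cartesian and shift operators for a spin of quantum number ``S``.

    Returns a dict with keys ``x, y, z, p, m, id`` in the Zeeman eigenbasis
    ordered ``m = S .. -S``.  Only S = 1/2 and S = 1 are supported.
    """
    if S not in (0.5, 1.0):
        raise ValueError(f"unsupported spin quantum number S={S}; only 1/2 and 1")
    dim = int(round(2 * S + 1))
    m = S - np.arange(dim)
    sz = np.diag(m).astype(complex)
    # <m+1| S+ |m> = sqrt(S(S+1) - m(m+1))
    cp = np.sqrt(S * (S + 1) - m[1:] * (m[1:] + 1))
    sp = np.zeros((dim, dim), complex)
    sp[np.arange(dim - 1), np.arange(1, dim)] = cp
    sm = sp.conj().T
    sx = (sp + sm) / 2
    sy = (sp - sm) / 2j
    return {"x": sx, "y": sy, "z": sz, "p": sp, "m": sm,
            "id": np.eye(dim, dtype=complex)}


_TOP_COEFF = {1: -1 / np.sqrt(2), 2: 0.5}


def irreducible_tensors(S: float, l: int) -> list[np.ndarray]:
    """Irreducible spherical tensor operators ``T_{l,k}``, k = -l..+l.

    Built from the highest-weight component ``T_{l,l} = c_l S_+^l`` by
    repeated lowering ``T_{l,k-1} = [S_-, T_{l,k}] / sqrt(l(l+1)-k(k-1))``,
    with ``c_1 = -1/sqrt(2)`` and ``c_2 = 1/2`` (the convention stated in
    the module docstring).
    """
    if l > int(round(2 * S)):
        raise ValueError(f"rank l={l} exceeds 2S={2 * S}")
    ops = spin_operators(S)
    if l == 0:
        return [ops["id"]]
    if l > 2:
        raise ValueError("ranks above 2 are not supported")
    top = _TOP_COEFF[l] * np.linalg.matrix_power(ops["p"], l)
    tensors = [top]
    for k in range(l, -l, -1):
        low = (ops["m"] @ tensors[0] - tensors[0] @ ops["m"])
        low /= np.sqrt(l * (l + 1) - k * (k - 1))
        tensors.insert(0, low)
    return tensors


def pair_tensors(S1: float, S2: float) -> list[np.ndarray]:
    """Rank-2 spherical tensor operators of a spin pair, k = -2..+2.

    T_{2,0}   = (3 I_z S_z - I.S)/sqrt(6),
    T_{2,+-1} = -+ (I_z S+- + I+- S_z)/2,
    T_{2,+-2} = I+- S+- / 2,
    on the product space ``spin1 (x) spin2``.
    """
    a, b = spin_operators(S1), spin_operators(S2)

    def kr(p, q):
        return np.kron(p, q)

    idot = kr(a["x"], b["x"]) + kr(a["y"], b["y"]) + kr(a["z"], b["z"])
    t20 = (3 * kr(a["z"], b["z"]) - idot) / np.sqrt(6)
    t2p1 = -(kr(a["z"], b["p"]) + kr(a["p"], b["z"])) / 2
    t2m1 = (kr(a["z"], b["m"]) + kr(a["m"], b["z"])) / 2
    t2p2 = kr(a["p"], b["p"]) / 2
    t2m2 = kr(a["m"], b["m"]) / 2
    return [t2m2, t2m1, t20, t2p1, t2p2]


def spin_rotation(S: float, euler: tuple[float, float, float]) -> np.ndarray:
    """Active ZYZ rotation operator exp(-ia Sz) exp(-ib Sy) exp(-ig Sz)."""
    ops = spin_operators(S)
    a, b, g = euler
    return (expm(-1j * a * ops["z"]) @ expm(-1j * b * ops["y"])
            @ expm(-1j * g * ops["z"]))


# ---------------------------------------------------------------------------
# Wigner rotation matrices
# ---------------------------------------------------------------------------

def _angmom(l: int) -> dict[str, np.ndarray]:
    """Angular momentum matrices of rank ``l`` in the |l,k> basis, k=-l..+l."""
    k = np.arange(-l, l + 1)
    jz = np.diag(k).astype(complex)
    jp = np.zeros((2 * l + 1, 2 * l + 1), complex)
    # <k+1| J+ |k>
    jp[np.arange(1, 2 * l + 1), np.arange(2 * l)] = np.sqrt(
        l * (l + 1) - k[:-1] * (k[:-1] + 1))
    jm = jp.conj().T
    jy = (jp - jm) / 2j
    return {"z": jz, "y": jy, "p": jp, "m": jm, "x": (jp + jm) / 2}


def wigner_d(l: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Wigner matrix ``D^l_{k',k}(alpha,beta,gamma)`` indexed k = -l..+l.

    ``D^l_{k'k} = exp(-i k' alpha) d^l_{k'k}(beta) exp(-i k gamma)`` with the
    ZYZ active convention of the module docstring.
    """
    j = _angmom(l)
    return (expm(-1j * alpha * j["z"]) @ expm(-1j * beta * j["y"])
            @ expm(-1j * gamma * j["z"]))


def wigner_d2(euler: tuple[float, float, float]) -> np.ndarray:
    """Rank-2 Wigner rotation matrix for a ZYZ Euler triple."""
    return wigner_d(2, *euler)


def wigner_d2_axis(axis, phi: float) -> np.ndarray:
    """Rank-2 Wigner matrix in angle-axis parameterization.

    Rotation by angle ``phi`` about the unit vector ``axis``; for the z axis
    this is ``diag(exp(-i k phi))``, k = -2..+2.
    """
    axis = np.asarray(axis, float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-10:
        raise ValueError("rotation axis must be unit-norm")
    j = _angmom(2)
    n_dot_j = axis[0] * j["x"] + axis[1] * j["y"] + axis[2] * j["z"]
    return expm(-1j * phi * n_dot_j)


# ---------------------------------------------------------------------------
# spherical tensor sets (spatial parts of interactions)
# ---------------------------------------------------------------------------

@dataclass
class SphericalTensorSet:
    """Five irreducible rank-2 spatial components of one interaction.

    ``components[k + 2]`` is ``a_k`` in angular frequency units (rad/s);
    ``frame`` tags the reference frame ("pas", "molecular" or "lab").
    """

    components: np.ndarray
    frame: str = "pas"

    def __post_init__(self):
        self.components = np.asarray(self.components, complex)
        if self.components.shape != (5,):
            raise ValueError("rank-2 tensor set needs exactly 5 components")

    @property
    def norm2(self) -> float:
        """Rotational invariant sum_k |a_k|^2."""
        return float(np.sum(np.abs(self.components) ** 2))

    def is_hermitian(self, tol: float = 1e-9) -> bool:
        """Check a_{-k} = (-1)^k conj(a_k), i.e. Hermitian Hamiltonian term."""
        a = self.components
        for k in range(-2, 3):
            if abs(a[-k + 2] - (-1) ** k * np.conj(a[k + 2])) > tol * max(
                    1.0, np.abs(a).max()):
                return False
        return True


def rotate_components(a: SphericalTensorSet, rotation,
                      to_frame: str | None = None) -> SphericalTensorSet:
    """Rotate a spherical tensor set: ``a'_{k'} = sum_k D^2_{k'k} a_k``.

    ``rotation`` is either a ZYZ Euler triple or a ready-made 5x5 rank-2
    rotation matrix.  Hermiticity and the rotational invariant
    ``sum |a_k|^2`` are preserved (the matrix is unitary).
    """
    if isinstance(rotation, np.ndarray) and rotation.shape == (5, 5):
        d = rotation
    else:
        d = wigner_d2(tuple(rotation))
    return SphericalTensorSet(d @ a.components,
                              frame=to_frame or a.frame)


def quad_pas_components(cq_hz: float, eta: float, S: float = 1.0
                        ) -> SphericalTensorSet:
    """PAS spherical components of the quadrupolar interaction.

    ``H_Q = sum_k a_k T_{2,k}`` with ``a_0 = sqrt(6) * 2*pi*C_Q / (4S(2S-1))``
    and ``a_{+-2} = eta * 2*pi*C_Q / (4S(2S-1))`` (a_{+-1} = 0 in the PAS),
    which for S=1 reproduces H_Q = (2 pi C_Q/4)[3Sz^2 - S(S+1) +
    eta (Sx^2 - Sy^2)].
    """
    if S != 1.0:
        raise ValueError("quadrupole requires S = 1")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("asymmetry parameter must lie in [0, 1]")
    scale = 2 * np.pi * cq_hz / (4 * S * (2 * S - 1))
    a = np.zeros(5, complex)
    a[2] = np.sqrt(6) * scale
    a[0] = a[4] = eta * scale
    return SphericalTensorSet(a, frame="pas")


def csa_pas_components(sigma_iso_ppm: float, delta_sigma_ppm: float,
                       eta: float, omega_z: float
                       ) -> tuple[SphericalTensorSet, float]:
    """PAS components of the shielding anisotropy plus the isotropic shift.

    Haeberlen parameters: ``zeta = sigma_zz - sigma_iso = (2/3) delta_sigma``
    and ``eta = (sigma_yy - sigma_xx)/zeta``.  The anisotropic part is
    returned as spatial components ``a_0 = sqrt(3/2) omega_z zeta`` and
    ``a_{+-2} = -omega_z zeta eta / 2`` (rad/s, ppm folded in); its spin
    counterpart is the secular one-spin operator ``sqrt(2/3) Sz`` carried by
    the k = 0 lab component only.  The isotropic shift ``omega_z *
    sigma_iso`` (rad/s) is returned separately.
    """
    zeta = 2.0 / 3.0 * delta_sigma_ppm * 1e-6
    a = np.zeros(5, complex)
    a[2] = np.sqrt(1.5) * omega_z * zeta
    a[0] = a[4] = -0.5 * omega_z * zeta * eta
    iso = omega_z * sigma_iso_ppm * 1e-6
    return SphericalTensorSet(a, frame="pas"), iso


def dipolar_constant(r_angstrom: float, gamma1: float, gamma2: float) -> float:
    """Dipole-dipole coupling constant ``b`` in Hz.

    ``b = -(mu0/4pi) gamma1 gamma2 hbar / r^3 / (2 pi)``; negative for two
    positive-gamma nuclei.  For 1H-14N at 1.06 A, |b| is about 7.29 kHz.
    """
    if r_angstrom <= 0:
        raise ValueError("internuclear distance must be positive")
    r = r_angstrom * 1e-10
    return -(MU0 / (4 * np.pi)) * gamma1 * gamma2 * HBAR / r ** 3 / (2 * np.pi)


# ---------------------------------------------------------------------------
# superoperators
# ---------------------------------------------------------------------------

def commutation_superop(h: np.ndarray) -> np.ndarray:
    """Commutation superoperator of ``h`` acting on row-major vec(rho).

    ``vec([H, rho]) = (H (x) 1 - 1 (x) H^T) vec(rho)``.
    """
    h = np.asarray(h)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("Hamiltonian must be square")
    eye = np.eye(h.shape[0])
    return np.kron(h, eye) - np.kron(eye, h.T)


# ---------------------------------------------------------------------------
# spin system description
# ---------------------------------------------------------------------------

@dataclass
class Quadrupole:
    """Quadrupolar interaction: C_Q (Hz), asymmetry, PAS->molecular Euler."""
    cq_hz: float
    eta: float
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("0 <= eta_Q <= 1 required")


@dataclass
class CSA:
    """Shielding: isotropic shift, Haeberlen anisotropy, asymmetry (ppm)."""
    sigma_iso_ppm: float
    delta_sigma_ppm: float = 0.0
    eta: float = 0.0
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("0 <= eta_CSA <= 1 required")


@dataclass
class Dipole:
    """Dipole-dipole coupling between spins ``i`` and ``j``.

    Specified either through the internuclear distance (Angstrom) or the
    coupling constant b (Hz); Euler angles orient the internuclear vector
    in the molecular frame (the 14N quadrupole PAS for the fixtures).
    """
    i: int
    j: int
    r_angstrom: float | None = None
    b_hz: float | None = None
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if (self.r_angstrom is None) == (self.b_hz is None):
            raise ValueError("give exactly one of r_angstrom and b_hz")
        if self.r_angstrom is not None and self.r_angstrom <= 0:
            raise ValueError("internuclear distance must be positive")


@dataclass
class SpinSystem:
    """A small spin system with one lab-frame spin-1 nucleus.

    ``spins`` is a list of isotope labels; ``zeeman_hz`` the signed Larmor
    frequencies in Hz.  The (single) spin-1 nucleus is simulated in the
    laboratory frame; all spin-1/2 nuclei are kept in their rotating frames
    and every interaction touching them is truncated to the part that
    commutes with their Zeeman operator.
    """

    spins: list[str]
    zeeman_hz: list[float]
    quadrupole: dict[int, Quadrupole] = field(default_factory=dict)
    csa: dict[int, CSA] = field(default_factory=dict)
    dipoles: list[Dipole] = field(default_factory=list)

    def __post_init__(self):
        if len(self.spins) != len(self.zeeman_hz):
            raise ValueError("one Larmor frequency per spin required")
        for iso in self.spins:
            if iso not in SPIN:
                raise ValueError(f"unknown isotope {iso!r}")
        if sum(1 for iso in self.spins if SPIN[iso] == 1.0) != 1:
            raise ValueError("exactly one spin-1 nucleus is supported")
        for i in self.quadrupole:
            if SPIN[self.spins[i]] != 1.0:
                raise ValueError("quadrupole on a spin-1/2 nucleus")

    @property
    def spin_quantum_numbers(self) -> list[float]:
        return [SPIN[iso] for iso in self.spins]

    @property
    def dims(self) -> list[int]:
        return [int(round(2 * SPIN[iso] + 1)) for iso in self.spins]

    @property
    def dim(self) -> int:
        return int(np.prod(self.dims))

    @property
    def observed(self) -> int:
        """Index of the lab-frame (spin-1) nucleus."""
        return next(i for i, iso in enumerate(self.spins)
                    if SPIN[iso] == 1.0)

    def operator(self, i: int, name: str) -> np.ndarray:
        """Single-spin operator embedded into the full Hilbert space."""
        mats = []
        for j, iso in enumerate(self.spins):
            ops = spin_operators(SPIN[iso])
            mats.append(ops[name] if j == i else ops["id"])
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    def with_dipole_scaled(self, factor: float) -> "SpinSystem":
        """Copy of the system with every dipolar coupling scaled."""
        new = []
        for d in self.dipoles:
            b = d.b_hz if d.b_hz is not None else dipolar_constant(
                d.r_angstrom, GAMMA[self.spins[d.i]], GAMMA[self.spins[d.j]])
            new.append(replace(d, r_angstrom=None, b_hz=b * factor))
        return replace(self, dipoles=new)
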