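"""Fokker-Planck embedding: rotor orientation as a lab-space coordinate.

Instead of expanding over rotor-phase Fourier modes per crystallite, the
full orientation ``Omega`` of the sample is promoted to an explicit degree
of freedom, expanded over normalized Wigner functions ``D^j_{mn}(Omega)``
up to rank ``l`` -- the dimension factor is ``sum_j (2j+1)^2 =
(1+l)(1+2l)(3+2l)/3``.  Magic-angle spinning becomes the static transport
generator ``omega_MAS (n . L)`` built from lab-space angular-momentum
operators acting on the first Wigner index, with the spinning axis ``n``
tilted by the magic angle.  Spherical powder averaging is implicit: a
uniform orientation distribution is the ``j = 0`` basis function, so
embedding and detecting there performs the three-angle average with no
orientation loop.

The Floquet and Fokker-Planck pictures give identical powder spectra; this
module provides the independent route for that cross-check (free evolution
of a prepared state).  Pulsed sequences run on the Floquet path, whose
per-orientation matrices stay small enough for dense effective-Hamiltonian
algebra.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .constants import MAGIC_ANGLE
from .floquet import InteractionTerms, interaction_terms
from .spin import SpinSystem

__all__ = ["fokker_planck_dimension_factor", "FokkerPlanckSpace"]


def fokker_planck_dimension_factor(l: int) -> int:
    """Dimension increase ``(1+l)(1+2l)(3+2l)/3`` of the embedding."""
    return (1 + l) * (1 + 2 * l) * (3 + 2 * l) // 3


@lru_cache(maxsize=None)
def _w3j(j1, j2, j3, m1, m2, m3) -> float:
    from sympy.physics.wigner import wigner_3j
    return float(wigner_3j(j1, j2, j3, m1, m2, m3))


def _wigner_basis(l: int) -> list[tuple[int, int, int]]:
    return [(j, m, n) for j in range(l + 1)
            for m in range(-j, j + 1) for n in range(-j, j + 1)]


def _mult_operator(l: int, k: int, kp: int) -> sp.csr_matrix:
    """Multiplication by ``D^2_{k,kp}(Omega)`` on normalized Wigner functions.

    ``<j1 m1 n1| D^2_{k kp} |j2 m2 n2> = sqrt((2j1+1)(2j2+1))
    (-1)^(m1-n1) (j1 2 j2; -m1 k m2)(j1 2 j2; -n1 kp n2)``.
    """
    basis = _wigner_basis(l)
    index = {b: i for i, b in enumerate(basis)}
    rows, cols, vals = [], [], []
    for i2, (j2, m2, n2) in enumerate(basis):
        for j1 in range(abs(j2 - 2), min(l, j2 + 2) + 1):
            m1 = m2 + k
            n1 = n2 + kp
            if abs(m1) > j1 or abs(n1) > j1:
                continue
            c = (np.sqrt((2 * j1 + 1) * (2 * j2 + 1))
                 * (-1) ** (m1 - n1)
                 * _w3j(j1, 2, j2, -m1, k, m2)
                 * _w3j(j1, 2, j2, -n1, kp, n2))
            if abs(c) > 1e-14:
                rows.append(index[(j1, m1, n1)])
                cols.append(i2)
                vals.append(c)
    dim = len(basis)
    return sp.csr_matrix((vals, (rows, cols)), shape=(dim, dim))


def _transport_generator(l: int) -> sp.csr_matrix:
    """``n . L`` for the magic-angle spinning axis, on the first index."""
    basis = _wigner_basis(l)
    index = {b: i for i, b in enumerate(basis)}
    dim = len(basis)
    lz = sp.lil_matrix((dim, dim))
    lx = sp.lil_matrix((dim, dim))
    for i, (j, m, n) in enumerate(basis):
        lz[i, i] = m
        if m + 1 <= j:
            c = np.sqrt(j * (j + 1) - m * (m + 1))
            lx[index[(j, m + 1, n)], i] += 0.5 * c
        if m - 1 >= -j:
            c = np.sqrt(j * (j + 1) - m * (m - 1))
            lx[index[(j, m - 1, n)], i] += 0.5 * c
    return (np.cos(MAGIC_ANGLE) * lz.tocsr()
            + np.sin(MAGIC_ANGLE) * lx.tocsr())


class FokkerPlanckSpace:
    """Fokker-Planck generator for a spinning powder.

    The Hermitian evolution matrix (generator ``-iF``) is

        F = sum_int sum_{k,kp} a^mol_kp [D^2_{k,kp}]_x (x) (O_k (x) 1 -
            1 (x) O_k^T)  +  1_x (x) L_static  -  omega_MAS (n.L) (x) 1 ,

    acting on (Wigner functions up to rank ``l``) (x) (spin Liouville
    space).  The transport sign follows from the co-moving density
    derivation and is pinned by the Floquet equivalence test.
    """

    def __init__(self, system: SpinSystem, rank: int, omega_mas: float,
                 terms: InteractionTerms | None = None):
        self.system = system
        self.rank = int(rank)
        self.omega_mas = float(omega_mas)
        self.terms = terms if terms is not None else interaction_terms(system)
        self.dim_spin = self.terms.dim
        self.dim_space = fokker_planck_dimension_factor(self.rank)
        self.dim = self.dim_space * self.dim_spin ** 2
        self._f: sp.csr_matrix | None = None

    def evolution_matrix(self) -> sp.csr_matrix:
        if self._f is None:
            l = self.rank
            d = self.dim_spin
            eye_spin = np.eye(d)
            eye_space = sp.identity(self.dim_space, format="csr")

            def superop(h):
                return sp.csr_matrix(np.kron(h, eye_spin)
                                     - np.kron(eye_spin, h.T))

            f = sp.csr_matrix((self.dim, self.dim), dtype=complex)
            # interactions: molecular-frame components against D^2 columns;
            # the spin operator of lab component k is recovered from the
            # magic-angle-folded B[m] via the inverse tilt, so build from
            # the raw O_k route instead: B was tilted for the Floquet rotor
            # chain, while here D^2(Omega) already maps molecule -> lab.
            for a_mol, o_lab in self._lab_terms():
                for k in range(-2, 3):
                    lk = superop(o_lab[k + 2])
                    if abs(lk).max() == 0:
                        continue
                    for kp in range(-2, 3):
                        if abs(a_mol[kp + 2]) < 1e-12:
                            continue
                        mult = _mult_operator(l, k, kp)
                        if mult.nnz == 0:
                            continue
                        f = f + a_mol[kp + 2] * sp.kron(mult, lk, format="csr")
            f = f + sp.kron(eye_space, superop(self.terms.static),
                            format="csr")
            # transport sign matches the rotor rotation sense fixed in
            # floquet.fourier_blocks (sideband-asymmetry convention)
            f = f + self.omega_mas * sp.kron(
                _transport_generator(l),
                sp.identity(d * d, format="csr"), format="csr")
            # the generator is -iF with F Hermitian; enforce symmetry lost
            # to rounding in the 3j arithmetic
            f = (f + f.conj().T) * 0.5
            self._f = f.tocsr()
        return self._f

    def _lab_terms(self):
        """Raw lab spin tensors (molecule -> lab covered by D^2(Omega))."""
        return [(a_mol, o_k) for a_mol, o_k, _b in self.terms.terms]

    # -- states -------------------------------------------------------------

    def embed_state(self, rho: np.ndarray) -> np.ndarray:
        """Uniform orientation distribution: state in the j = 0 block."""
        vec = np.zeros(self.dim, complex)
        d2 = self.dim_spin ** 2
        vec[:d2] = rho.reshape(-1)  # basis ordering starts at (0,0,0)
        return vec

    def detect_vector(self, op: np.ndarray) -> np.ndarray:
        return self.embed_state(op)

    def spectrum(self, rho_vec: np.ndarray, detect: np.ndarray,
                 omega_list: np.ndarray, r: float) -> np.ndarray:
        """Powder spectrum by per-frequency sparse direct solves."""
        from .detect import fd_spectrum
        return fd_spectrum(self.evolution_matrix(), r, rho_vec, detect,
                           omega_list, method="solve")
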