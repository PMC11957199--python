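"""Brute-force second-quantization oracles.

Everything here is built directly from Jordan-Wigner creation/annihilation
matrices on the full 4^M Fock space and stays independent of the package's
determinant machinery: spin-orbital j (alpha orbitals 0..M-1, then beta
orbitals M..2M-1) maps to qubit j, a Fock basis index equals the packed
2M-bit configuration, and operators are assembled as explicit matrices.
Only viable for M <= 4 or so; that is the point.
"""

from __future__ import annotations

from functools import reduce

import numpy as np

_CREATE = np.array([[0.0, 0.0], [1.0, 0.0]])
_Z = np.diag([1.0, -1.0])
_I2 = np.eye(2)


def creation_ops(m: int) -> list[np.ndarray]:
    """JW creation matrices for 2M spin-orbitals; bit j of the Fock index
    is the occupation of spin-orbital j."""
    nq = 2 * m
    ops = []
    for j in range(nq):
        factors = [_I2] * (nq - 1 - j) + [_CREATE] + [_Z] * j
        ops.append(reduce(np.kron, factors))
    return ops


def fock_hamiltonian(ham) -> np.ndarray:
    """Dense Fock-space matrix of the active-space Hamiltonian."""
    m = ham.m
    cr = creation_ops(m)
    an = [c.T for c in cr]
    dim = 4**m
    out = ham.e0 * np.eye(dim)
    for sigma in (0, m):
        for p in range(m):
            for r in range(m):
                if ham.h[p, r] != 0.0:
                    out += ham.h[p, r] * cr[p + sigma] @ an[r + sigma]
    for sigma in (0, m):
        for tau in (0, m):
            for p in range(m):
                for r in range(m):
                    for q in range(m):
                        for s in range(m):
                            v = ham.eri[p, r, q, s]
                            if v != 0.0:
                                out += (
                                    0.5
                                    * v
                                    * cr[p + sigma]
                                    @ cr[q + tau]
                                    @ an[s + tau]
                                    @ an[r + sigma]
                                )
    return out


def sector_indices(subspace) -> np.ndarray:
    """Fock indices of a determinant subspace, in its alpha-major order."""
    m = subspace.m
    return np.array(
        [
            a | (b << m)
            for a in subspace.alpha_strings
            for b in subspace.beta_strings
        ],
        dtype=np.int64,
    )


def sector_hamiltonian(ham, subspace) -> np.ndarray:
    """Dense Hamiltonian restricted to the subspace's determinants."""
    idx = sector_indices(subspace)
    return fock_hamiltonian(ham)[np.ix_(idx, idx)]


def one_body_operator(k_mat: np.ndarray, m: int) -> np.ndarray:
    """Fock matrix of sum_{pr,sigma} K_pr a†_{p sigma} a_{r sigma}."""
    cr = creation_ops(m)
    an = [c.T for c in cr]
    dim = 4**m
    out = np.zeros((dim, dim), dtype=complex)
    for sigma in (0, m):
        for p in range(m):
            for r in range(m):
                if k_mat[p, r] != 0.0:
                    out += k_mat[p, r] * cr[p + sigma] @ an[r + sigma]
    return out


def number_operator(p: int, sigma: int, m: int) -> np.ndarray:
    cr = creation_ops(m)
    j = p + (m if sigma else 0)
    return cr[j] @ cr[j].T


def t2_operator(t2: np.ndarray, m: int) -> np.ndarray:
    """Fock matrix of T2 = 1/2 sum_{ijab} t2[i,j,a,b] E_{ai} E_{bj}."""
    nocc = t2.shape[0]
    cr = creation_ops(m)
    an = [c.T for c in cr]
    dim = 4**m

    def e_op(p, r):
        out = np.zeros((dim, dim))
        for sigma in (0, m):
            out += cr[p + sigma] @ an[r + sigma]
        return out

    out = np.zeros((dim, dim))
    for i in range(nocc):
        for j in range(nocc):
            for a in range(t2.shape[2]):
                for b in range(t2.shape[3]):
                    if t2[i, j, a, b] != 0.0:
                        out += (
                            0.5
                            * t2[i, j, a, b]
                            * e_op(nocc + a, i)
                            @ e_op(nocc + b, j)
                        )
    return out


def density_matrix_diagonal(psi_coeffs, subspace) -> np.ndarray:
    """Spin-orbital occupations via explicit number operators."""
    m = subspace.m
    idx = sector_indices(subspace)
    dim = 4**m
    full = np.zeros(dim, dtype=complex)
    full[idx] = psi_coeffs
    out = []
    for sigma in (0, 1):
        for p in range(m):
            n_op = number_operator(p, sigma, m)
            out.append(float(np.real(full.conj() @ (n_op @ full))))
    return np.array(out)
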