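"""Truncated local unitary cluster Jastrow (LUCJ) ansatz.

The ansatz approximates the active-space ground state as

    |Psi> = e^{-K2} e^{K1} e^{iJ1} e^{-K1} |x_RHF>,

i.e. a "1.5-layer" truncation of the unitary cluster Jastrow product of
orbital rotations e^{K} (one-body) and diagonal density-density phase
layers e^{iJ}, applied to the restricted Hartree-Fock determinant.  It is
parameterized from closed-shell CCSD doubles amplitudes t2 through a
double factorization:

    T2 = 1/2 sum_k lam_k A_k^2,  A_k = sum_ia V_k[i,a] E_{ai},

where (lam_k, V_k) are the eigenpairs of the symmetric matrix
t2[(ia),(jb)].  Writing A = (S + D)/2 with S = A + A^T symmetric and
D = A - A^T antisymmetric gives the operator identity

    A^2 - (A†)^2 = i/2 [ (X+)^2 - (X-)^2 ],   X± = S ∓ i D,

so that e^{T2 - T2†} factorizes (to first order in a Trotter splitting)
into rotated diagonal-Coulomb factors U e^{iJ} U† with U diagonalizing
the Hermitian one-body matrices X± and J = ±(lam_k/8) w w^T built from
their eigenvalues w.  The truncated form retains the dominant factor in
full; the trailing half-layer rotation e^{-K2} carries the unitarized
singles amplitudes when supplied (and is zero otherwise, the default).
A locality mask zeroes density-density couplings between spin-orbital
pairs that are not adjacent on the emulated device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from . import _bits
from .errors import CapacityError
from .hamiltonian_io import ActiveSpaceHamiltonian, cas_dimension
from .determinant_ci import CIVector, DeterminantSubspace


@dataclass
class LUCJParameters:
    """Generators of the truncated ansatz.

    k1, k2 : complex anti-Hermitian M x M orbital-rotation generators
        (e^{K} unitary; both spin sectors rotated identically).
    j1 : real symmetric 2M x 2M density-density coupling matrix indexed
        by spin-orbital pairs (alpha block first).
    mask : boolean 2M x 2M locality pattern; j1 is zero outside it.
    """

    m: int
    k1: np.ndarray
    k2: np.ndarray
    j1: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = self.m
        self.k1 = np.asarray(self.k1, dtype=complex)
        self.k2 = np.asarray(self.k2, dtype=complex)
        self.j1 = np.asarray(self.j1, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.k1.shape != (m, m) or self.k2.shape != (m, m):
            raise ValueError("k1/k2 must be M x M")
        if self.j1.shape != (2 * m, 2 * m) or self.mask.shape != (2 * m, 2 * m):
            raise ValueError("j1/mask must be 2M x 2M")
        for k in (self.k1, self.k2):
            if not np.allclose(k, -k.conj().T, atol=1e-10):
                raise ValueError("orbital-rotation generators must be anti-Hermitian")
        if not np.allclose(self.j1, self.j1.T, atol=1e-10):
            raise ValueError("j1 must be symmetric")
        if np.any(self.j1[~self.mask] != 0.0):
            raise ValueError("j1 must vanish outside the locality mask")

    @classmethod
    def zero(cls, m: int, mask: np.ndarray | None = None) -> "LUCJParameters":
        if mask is None:
            mask = np.ones((2 * m, 2 * m), dtype=bool)
        z = np.zeros((m, m))
        return cls(m, z.astype(complex), z.astype(complex),
                   np.zeros((2 * m, 2 * m)), mask)


def lucj_mask(m: int, pattern: str) -> np.ndarray:
    """Locality pattern for density-density couplings.

    "dense": all pairs allowed.  "line_heavyhex": same-spin pairs allowed
    iff |p - r| <= 1 (neighbours on a line of qubits), opposite-spin pairs
    iff p == r (coupled through one auxiliary qubit), emulating the
    heavy-hex connectivity constraint.
    """
    if pattern == "dense":
        return np.ones((2 * m, 2 * m), dtype=bool)
    if pattern != "line_heavyhex":
        raise ValueError(f"unknown locality pattern {pattern!r}")
    mask = np.zeros((2 * m, 2 * m), dtype=bool)
    p_idx = np.arange(m)
    same = np.abs(p_idx[:, None] - p_idx[None, :]) <= 1
    mask[:m, :m] = same
    mask[m:, m:] = same
    opposite = np.eye(m, dtype=bool)
    mask[:m, m:] = opposite
    mask[m:, :m] = opposite
    return mask


# ---------------------------------------------------------------------------
# t2 double factorization
# ---------------------------------------------------------------------------


def ucj_factors(t2: np.ndarray, tol: float = 1e-12):
    """Rotated diagonal-Coulomb factorization of e^{T2 - T2†}.

    Returns a list of factors ``(Q, w, c)`` — complex unitary M x M
    rotation, real eigenvalue vector, real coupling scale — ordered so
    that the factor at index 0 acts *first* on the reference:

        e^{T2 - T2†} ≈ F[n-1] ... F[1] F[0],
        F = U_Q exp(i c (sum_{p,sigma} w_p n_{p,sigma})^2) U_Q†.

    Eigenvalues of the t2 matrix are taken in descending magnitude; each
    contributes a (+, -) pair of factors, the minus factor first.
    """
    t2 = np.asarray(t2, dtype=float)
    nocc, nocc2, nvrt, nvrt2 = t2.shape
    if nocc != nocc2 or nvrt != nvrt2:
        raise ValueError("t2 must have shape (nocc, nocc, nvirt, nvirt)")
    m = nocc + nvrt
    t2_mat = t2.transpose(0, 2, 1, 3).reshape(nocc * nvrt, nocc * nvrt)
    if not np.allclose(t2_mat, t2_mat.T, atol=1e-10):
        raise ValueError("t2 matrix (ia),(jb) must be symmetric")
    lams, vecs = np.linalg.eigh(t2_mat)
    order = np.argsort(-np.abs(lams))
    factors = []
    for k in order:
        lam = lams[k]
        if abs(lam) <= tol:
            continue
        v = vecs[:, k].reshape(nocc, nvrt)
        a_mat = np.zeros((m, m))
        a_mat[nocc:, :nocc] = v.T  # A[a, i] = V[i, a]
        s_mat = a_mat + a_mat.T
        d_mat = a_mat - a_mat.T
        for sign in (-1.0, +1.0):  # minus factor acts first
            x_mat = s_mat - sign * 1j * d_mat
            w, q = np.linalg.eigh(x_mat)
            factors.append((q, w, sign * lam / 8.0))
    return factors


def lucj_from_ccsd(
    t2: np.ndarray, mask: np.ndarray, t1: np.ndarray | None = None
) -> LUCJParameters:
    """Truncated 1.5-layer LUCJ parameters from CCSD amplitudes.

    The dominant factor of :func:`ucj_factors` supplies the inner rotation
    K1 and the density-density coupling J1 (zeroed outside ``mask``).  The
    trailing half layer e^{-K2} is the unitarized singles rotation
    e^{T1 - T1†} when ``t1`` is given; by default singles amplitudes are
    ignored and K2 = 0, so the ansatz reduces to a single full layer.
    """
    t2 = np.asarray(t2, dtype=float)
    nocc = t2.shape[0]
    nvrt = t2.shape[2]
    m = nocc + nvrt
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (2 * m, 2 * m):
        raise ValueError("mask must be 2M x 2M for M = nocc + nvirt")
    k2 = np.zeros((m, m), dtype=complex)
    if t1 is not None:
        t1 = np.asarray(t1, dtype=float)
        if t1.shape != (nocc, nvrt):
            raise ValueError("t1 must have shape (nocc, nvirt)")
        # e^{-K2} = e^{T1 - T1†}
        k2[nocc:, :nocc] = -t1.T
        k2[:nocc, nocc:] = t1
    factors = ucj_factors(t2)
    if not factors:
        return LUCJParameters.zero(m, mask) if t1 is None else LUCJParameters(
            m, np.zeros((m, m), complex), k2, np.zeros((2 * m, 2 * m)), mask
        )
    q1, w1, c1 = factors[0]
    k1 = scipy.linalg.logm(q1)
    k1 = (k1 - k1.conj().T) / 2
    w_spin = np.concatenate([w1, w1])
    j1 = c1 * np.outer(w_spin, w_spin)
    j1[~mask] = 0.0
    return LUCJParameters(m, k1, k2, j1, mask)


# ---------------------------------------------------------------------------
# exact state-vector evaluation over the CAS determinant space
# ---------------------------------------------------------------------------


def _one_body_ci_matrix(
    k_mat: np.ndarray, subspace: DeterminantSubspace
) -> sp.csr_matrix:
    """Sparse CI-space matrix of the one-body operator sum K_pr a†_ps a_rs."""
    m = subspace.m
    nb = len(subspace.beta_strings)
    rows, cols, vals = [], [], []
    diag_k = np.diag(k_mat)
    for ia, a in enumerate(subspace.alpha_strings):
        occ_a = _bits.occ_list(a, m)
        vir_a = _bits.vir_list(a, m)
        for ib, b in enumerate(subspace.beta_strings):
            j = ia * nb + ib
            occ_b = _bits.occ_list(b, m)
            diag = sum(diag_k[p] for p in occ_a) + sum(diag_k[p] for p in occ_b)
            rows.append(j)
            cols.append(j)
            vals.append(diag)
            for r in occ_a:  # alpha excitation r -> p
                for p in vir_a:
                    a2 = (a & ~(1 << r)) | (1 << p)
                    if subspace.contains(a2, b):
                        phase = _bits.excitation_phase(a, r, p)
                        rows.append(subspace.index(a2, b))
                        cols.append(j)
                        vals.append(phase * k_mat[p, r])
            occ_bv = _bits.vir_list(b, m)
            for r in occ_b:
                for p in occ_bv:
                    b2 = (b & ~(1 << r)) | (1 << p)
                    if subspace.contains(a, b2):
                        phase = _bits.excitation_phase(b, r, p)
                        rows.append(subspace.index(a, b2))
                        cols.append(j)
                        vals.append(phase * k_mat[p, r])
    d = subspace.dimension
    return sp.csr_matrix((vals, (rows, cols)), shape=(d, d), dtype=complex)


def _jastrow_phases(j1: np.ndarray, subspace: DeterminantSubspace) -> np.ndarray:
    """Diagonal phase exponents q(x) = x^T J x per determinant (alpha-major)."""
    m = subspace.m
    bits_a = np.array(
        [[(a >> p) & 1 for p in range(m)] for a in subspace.alpha_strings],
        dtype=float,
    )
    bits_b = np.array(
        [[(b >> p) & 1 for p in range(m)] for b in subspace.beta_strings],
        dtype=float,
    )
    jaa = np.einsum("ip,pq,jq->ij", bits_a, j1[:m, :m], bits_a)
    jbb = np.einsum("ip,pq,jq->ij", bits_b, j1[m:, m:], bits_b)
    jab = np.einsum("ip,pq,jq->ij", bits_a, j1[:m, m:], bits_b)
    # q(a, b) = a.Jaa.a + b.Jbb.b + 2 a.Jab.b (J symmetric)
    q = np.diag(jaa)[:, None] + np.diag(jbb)[None, :] + 2.0 * jab
    return q.reshape(-1)


def reference_determinant(m: int, n_alpha: int, n_beta: int) -> tuple[int, int]:
    """RHF-style reference: the lowest-index orbitals occupied per sector."""
    return (1 << n_alpha) - 1, (1 << n_beta) - 1


def apply_lucj(
    params: LUCJParameters,
    m: int,
    n_alpha: int,
    n_beta: int,
    max_dimension: int = 2_000_000,
) -> CIVector:
    """Evaluate the truncated LUCJ state exactly over the full CAS space.

    Orbital rotations are applied by Krylov propagation of the quadratic
    generator (one CI vector in memory); the Jastrow layer is a diagonal
    phase per determinant.  The result is normalized, complex, and
    supported only on correct-particle-number determinants by
    construction.
    """
    if params.m != m:
        raise ValueError("parameter dimension does not match M")
    d = cas_dimension(m, n_alpha, n_beta)
    if d > max_dimension:
        raise CapacityError(d, max_dimension)
    subspace = DeterminantSubspace.full(m, n_alpha, n_beta)
    ref_a, ref_b = reference_determinant(m, n_alpha, n_beta)
    v = np.zeros(d, dtype=complex)
    v[subspace.index(ref_a, ref_b)] = 1.0

    k1 = _one_body_ci_matrix(params.k1, subspace)
    v = expm_multiply(-k1, v)
    v = v * np.exp(1j * _jastrow_phases(params.j1, subspace))
    v = expm_multiply(k1, v)
    if np.any(params.k2 != 0):
        k2 = _one_body_ci_matrix(params.k2, subspace)
        v = expm_multiply(-k2, v)
    v /= np.linalg.norm(v)
    return CIVector(subspace, v)


def apply_ucj_factors(
    factors,
    m: int,
    n_alpha: int,
    n_beta: int,
    max_dimension: int = 2_000_000,
) -> CIVector:
    """Apply the *untruncated* factor product of :func:`ucj_factors`.

    Used to validate the factorization against the brute-force
    e^{T2 - T2†} reference; factor 0 acts first.
    """
    d = cas_dimension(m, n_alpha, n_beta)
    if d > max_dimension:
        raise CapacityError(d, max_dimension)
    subspace = DeterminantSubspace.full(m, n_alpha, n_beta)
    ref_a, ref_b = reference_determinant(m, n_alpha, n_beta)
    v = np.zeros(d, dtype=complex)
    v[subspace.index(ref_a, ref_b)] = 1.0
    bits_a = np.array(
        [[(a >> p) & 1 for p in range(m)] for a in subspace.alpha_strings],
        dtype=float,
    )
    bits_b = np.array(
        [[(b >> p) & 1 for p in range(m)] for b in subspace.beta_strings],
        dtype=float,
    )
    for q_mat, w, c in factors:
        k_gen = scipy.linalg.logm(q_mat)
        k_gen = (k_gen - k_gen.conj().T) / 2
        k_ci = _one_body_ci_matrix(k_gen, subspace)
        v = expm_multiply(-k_ci, v)  # rotate into the eigenbasis of X
        wa = bits_a @ w
        wb = bits_b @ w
        tot = (wa[:, None] + wb[None, :]).reshape(-1)
        v = v * np.exp(1j * c * tot**2)
        v = expm_multiply(k_ci, v)
    v /= np.linalg.norm(v)
    return CIVector(subspace, v)


def mp2_amplitudes(ham: ActiveSpaceHamiltonian) -> np.ndarray:
    """Perturbative doubles amplitudes from the active-space integrals.

    A self-contained stand-in used to parameterize the ansatz when no
    external coupled-cluster engine is available: closed-shell MP2-style
    amplitudes t2[i,j,a,b] = -(ia|jb) / (e_a + e_b - e_i - e_j) with
    orbital energies from the diagonal of the active-space Fock matrix
    built on the reference determinant.  Requires n_alpha == n_beta.
    """
    if ham.n_alpha != ham.n_beta:
        raise ValueError("closed-shell amplitudes require n_alpha == n_beta")
    nocc = ham.n_alpha
    nvrt = ham.m - nocc
    occ = list(range(nocc))
    fock = ham.h.copy()
    for q in occ:
        fock += 2.0 * ham.eri[:, :, q, q] - ham.eri[:, q, q, :]
    eps = np.diag(fock)
    t2 = np.zeros((nocc, nocc, nvrt, nvrt))
    for i in range(nocc):
        for j in range(nocc):
            for a in range(nvrt):
                for b in range(nvrt):
                    denom = eps[nocc + a] + eps[nocc + b] - eps[i] - eps[j]
                    if abs(denom) < 1e-8:
                        continue
                    t2[i, j, a, b] = -ham.eri[i, nocc + a, j, nocc + b] / denom
    return t2
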