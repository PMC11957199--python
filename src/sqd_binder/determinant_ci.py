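"""Determinant-basis CI engine.

Matrix elements of the active-space Hamiltonian between Slater
determinants follow the Slater-Condon rules with chemist-notation
integrals (pr|qs).  Spin-orbitals are ordered all-alpha (ascending
spatial orbital) then all-beta; because both sectors conserve particle
number separately, antisymmetry phases factorize per sector and are
computed by sequential application of creation/annihilation operators
on the occupation bitmasks.

Subspaces are Cartesian products A x B of unique alpha and beta
occupation strings — the structure produced by configuration recovery —
and the lowest eigenpair is found with a Davidson iteration
(diagonal preconditioner, restarted search space).  The Hamiltonian
variance ΔH = <ψ|H²|ψ> − <ψ|H|ψ>² is evaluated with the *unprojected*
Hamiltonian by exact enumeration of all single and double excitations
of the support, as required for energy-variance extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from . import _bits
from .errors import CapacityError, ConvergenceError
from .hamiltonian_io import ActiveSpaceHamiltonian, cas_dimension


@dataclass(frozen=True)
class Determinant:
    """Electronic configuration: one occupation bitmask per spin sector."""

    alpha: int
    beta: int

    def particle_numbers(self) -> tuple[int, int]:
        return _bits.popcount(self.alpha), _bits.popcount(self.beta)


@dataclass
class DeterminantSubspace:
    """Cartesian-product determinant space S = A x B.

    ``alpha_strings`` and ``beta_strings`` are sorted unique occupation
    masks; the implied determinants are all pairs, indexed alpha-major.
    """

    m: int
    alpha_strings: list[int]
    beta_strings: list[int]
    _a_index: dict[int, int] = field(init=False, repr=False)
    _b_index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.alpha_strings = sorted(set(int(a) for a in self.alpha_strings))
        self.beta_strings = sorted(set(int(b) for b in self.beta_strings))
        if not self.alpha_strings or not self.beta_strings:
            raise ValueError("subspace needs at least one string per sector")
        for strings in (self.alpha_strings, self.beta_strings):
            counts = {_bits.popcount(s) for s in strings}
            if len(counts) != 1:
                raise ValueError("mixed particle numbers within a spin sector")
        self._a_index = {a: i for i, a in enumerate(self.alpha_strings)}
        self._b_index = {b: i for i, b in enumerate(self.beta_strings)}

    @classmethod
    def full(cls, m: int, n_alpha: int, n_beta: int) -> "DeterminantSubspace":
        return cls(m, _bits.all_strings(m, n_alpha), _bits.all_strings(m, n_beta))

    @property
    def n_alpha(self) -> int:
        return _bits.popcount(self.alpha_strings[0])

    @property
    def n_beta(self) -> int:
        return _bits.popcount(self.beta_strings[0])

    @property
    def dimension(self) -> int:
        return len(self.alpha_strings) * len(self.beta_strings)

    def index(self, alpha: int, beta: int) -> int:
        return self._a_index[alpha] * len(self.beta_strings) + self._b_index[beta]

    def contains(self, alpha: int, beta: int) -> bool:
        return alpha in self._a_index and beta in self._b_index

    def determinants(self):
        for a in self.alpha_strings:
            for b in self.beta_strings:
                yield Determinant(a, b)


@dataclass
class CIVector:
    """Coefficients over a product subspace, indexed alpha-major."""

    subspace: DeterminantSubspace
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients)
        if self.coefficients.shape != (self.subspace.dimension,):
            raise ValueError("coefficient length must equal subspace dimension")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.coefficients))

    def require_normalized(self, tol: float = 1e-8) -> None:
        if abs(self.norm - 1.0) > tol:
            raise ValueError(f"state not normalized (norm {self.norm:.6g})")


@dataclass
class SubspaceResult:
    """Lowest eigenpair of a projected Hamiltonian plus derived quantities."""

    energy: float
    state: CIVector
    occupations: np.ndarray  # 2M entries, alpha block then beta block
    variance: float | None  # Hartree^2; None if not requested


# ---------------------------------------------------------------------------
# Slater-Condon matrix elements
# ---------------------------------------------------------------------------


def _diagonal_element(ham: ActiveSpaceHamiltonian, alpha: int, beta: int) -> float:
    occ_a = _bits.occ_list(alpha, ham.m)
    occ_b = _bits.occ_list(beta, ham.m)
    h, eri = ham.h, ham.eri
    e = ham.e0
    for p in occ_a:
        e += h[p, p]
    for p in occ_b:
        e += h[p, p]
    for p in occ_a:
        for q in occ_a:
            e += 0.5 * (eri[p, p, q, q] - eri[p, q, q, p])
    for p in occ_b:
        for q in occ_b:
            e += 0.5 * (eri[p, p, q, q] - eri[p, q, q, p])
    for p in occ_a:
        for q in occ_b:
            e += eri[p, p, q, q]
    return float(e)


def _single_element(
    ham: ActiveSpaceHamiltonian,
    p: int,
    r: int,
    same_occ: list[int],
    other_occ: list[int],
    phase: int,
) -> float:
    """<d|H|d_p^r> for a single excitation p->r within one spin sector.

    ``same_occ`` are the spectator occupied orbitals of the excited sector
    (i.e. occupied in both determinants), ``other_occ`` those of the
    opposite sector.
    """
    h, eri = ham.h, ham.eri
    val = h[p, r]
    for q in same_occ:
        val += eri[p, r, q, q] - eri[p, q, q, r]
    for q in other_occ:
        val += eri[p, r, q, q]
    return float(phase * val)


def _double_phase(mask: int, p: int, q: int, r: int, s: int) -> int:
    """Phase of a†_r a†_s a_q a_p on a single-sector mask."""
    m1, ph1 = _bits.annihilate(mask, p)
    m2, ph2 = _bits.annihilate(m1, q)
    m3, ph3 = _bits.create(m2, s)
    _, ph4 = _bits.create(m3, r)
    return ph1 * ph2 * ph3 * ph4


def slater_condon(
    ham: ActiveSpaceHamiltonian, d1: Determinant, d2: Determinant
) -> float:
    """Matrix element <d1|H|d2>, including E0 on the diagonal.

    Zero when the determinants differ in more than two spin-orbitals.
    """
    if d1.particle_numbers() != d2.particle_numbers():
        raise ValueError("determinants carry different particle numbers")
    m = ham.m
    diff_a = d1.alpha ^ d2.alpha
    diff_b = d1.beta ^ d2.beta
    na, nb = _bits.popcount(diff_a), _bits.popcount(diff_b)
    if na + nb > 4:
        return 0.0

    if na == 0 and nb == 0:
        return _diagonal_element(ham, d1.alpha, d1.beta)

    occ1_a = _bits.occ_list(d1.alpha, m)
    occ1_b = _bits.occ_list(d1.beta, m)

    if na == 2 and nb == 0:
        # single alpha excitation: d2 = a†_r a_p d1 pattern (p in d1, r in d2)
        p = _bits.occ_list(diff_a & d1.alpha, m)[0]
        r = _bits.occ_list(diff_a & d2.alpha, m)[0]
        phase = _bits.excitation_phase(d1.alpha, p, r)
        spect = [q for q in occ1_a if q != p]
        return _single_element(ham, p, r, spect, occ1_b, phase)
    if nb == 2 and na == 0:
        p = _bits.occ_list(diff_b & d1.beta, m)[0]
        r = _bits.occ_list(diff_b & d2.beta, m)[0]
        phase = _bits.excitation_phase(d1.beta, p, r)
        spect = [q for q in occ1_b if q != p]
        return _single_element(ham, p, r, spect, occ1_a, phase)

    eri = ham.eri
    if na == 4 and nb == 0:
        p, q = _bits.occ_list(diff_a & d1.alpha, m)
        r, s = _bits.occ_list(diff_a & d2.alpha, m)
        phase = _double_phase(d1.alpha, p, q, r, s)
        return float(phase * (eri[p, r, q, s] - eri[p, s, q, r]))
    if nb == 4 and na == 0:
        p, q = _bits.occ_list(diff_b & d1.beta, m)
        r, s = _bits.occ_list(diff_b & d2.beta, m)
        phase = _double_phase(d1.beta, p, q, r, s)
        return float(phase * (eri[p, r, q, s] - eri[p, s, q, r]))
    # one single excitation in each sector
    p = _bits.occ_list(diff_a & d1.alpha, m)[0]
    r = _bits.occ_list(diff_a & d2.alpha, m)[0]
    q = _bits.occ_list(diff_b & d1.beta, m)[0]
    s = _bits.occ_list(diff_b & d2.beta, m)[0]
    phase = _bits.excitation_phase(d1.alpha, p, r) * _bits.excitation_phase(
        d1.beta, q, s
    )
    return float(phase * eri[p, r, q, s])


def connected_elements(ham: ActiveSpaceHamiltonian, alpha: int, beta: int):
    """Yield ((alpha', beta'), <x'|H|x>) over all single/double excitations.

    The diagonal element is not yielded.  Every connected determinant of
    the full fixed-particle-number space appears exactly once.
    """
    m = ham.m
    eri = ham.eri
    occ_a = _bits.occ_list(alpha, m)
    vir_a = _bits.vir_list(alpha, m)
    occ_b = _bits.occ_list(beta, m)
    vir_b = _bits.vir_list(beta, m)

    # single excitations
    singles_a = []
    for p in occ_a:
        spect = [q for q in occ_a if q != p]
        for r in vir_a:
            phase = _bits.excitation_phase(alpha, p, r)
            val = _single_element(ham, p, r, spect, occ_b, phase)
            a2 = (alpha & ~(1 << p)) | (1 << r)
            singles_a.append((p, r, a2, phase))
            yield (a2, beta), val
    singles_b = []
    for p in occ_b:
        spect = [q for q in occ_b if q != p]
        for r in vir_b:
            phase = _bits.excitation_phase(beta, p, r)
            val = _single_element(ham, p, r, spect, occ_a, phase)
            b2 = (beta & ~(1 << p)) | (1 << r)
            singles_b.append((p, r, b2, phase))
            yield (alpha, b2), val

    # same-spin double excitations
    for occ, vir, mask, is_alpha in (
        (occ_a, vir_a, alpha, True),
        (occ_b, vir_b, beta, False),
    ):
        for p, q in combinations(occ, 2):
            for r, s in combinations(vir, 2):
                phase = _double_phase(mask, p, q, r, s)
                val = float(phase * (eri[p, r, q, s] - eri[p, s, q, r]))
                mask2 = (mask & ~((1 << p) | (1 << q))) | (1 << r) | (1 << s)
                if is_alpha:
                    yield (mask2, beta), val
                else:
                    yield (alpha, mask2), val

    # opposite-spin double excitations (one single in each sector)
    for p, r, a2, ph_a in singles_a:
        for q, s, b2, ph_b in singles_b:
            yield (a2, b2), float(ph_a * ph_b * eri[p, r, q, s])


# ---------------------------------------------------------------------------
# Projected Hamiltonian, Davidson, occupations, variance
# ---------------------------------------------------------------------------


def hamiltonian_matrix(
    ham: ActiveSpaceHamiltonian, subspace: DeterminantSubspace
) -> sp.csr_matrix:
    """Sparse matrix of P_S H P_S in the subspace basis (alpha-major)."""
    nb = len(subspace.beta_strings)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for ia, a in enumerate(subspace.alpha_strings):
        for ib, b in enumerate(subspace.beta_strings):
            j = ia * nb + ib
            rows.append(j)
            cols.append(j)
            vals.append(_diagonal_element(ham, a, b))
            for (a2, b2), val in connected_elements(ham, a, b):
                if val != 0.0 and subspace.contains(a2, b2):
                    rows.append(subspace.index(a2, b2))
                    cols.append(j)
                    vals.append(val)
    d = subspace.dimension
    return sp.csr_matrix((vals, (rows, cols)), shape=(d, d))


def apply_hamiltonian(
    ham: ActiveSpaceHamiltonian, v: CIVector, mode: str = "projected"
):
    """Hamiltonian action on a CI vector.

    mode="projected": returns P_S H P_S v as a :class:`CIVector` on the
    same subspace.  mode="full": returns H v as a dict mapping
    ``(alpha, beta)`` masks to amplitudes, supported on S plus all
    determinants connected to S by single/double excitations (the support
    needed by the variance).
    """
    if mode not in ("projected", "full"):
        raise ValueError("mode must be 'projected' or 'full'")
    S = v.subspace
    if mode == "projected":
        out = hamiltonian_matrix(ham, S) @ v.coefficients
        return CIVector(S, out)
    acc: dict[tuple[int, int], complex] = {}
    nb = len(S.beta_strings)
    c = v.coefficients
    for ia, a in enumerate(S.alpha_strings):
        for ib, b in enumerate(S.beta_strings):
            cj = c[ia * nb + ib]
            if cj == 0:
                continue
            key = (a, b)
            acc[key] = acc.get(key, 0.0) + _diagonal_element(ham, a, b) * cj
            for key2, val in connected_elements(ham, a, b):
                if val != 0.0:
                    acc[key2] = acc.get(key2, 0.0) + val * cj
    return acc


def occupations(psi: CIVector) -> np.ndarray:
    """Spin-orbital occupation numbers n_p(sigma) = <psi|n̂_p(sigma)|psi>.

    Returned as a length-2M vector, alpha block then beta block; per-spin
    sums equal the sector particle numbers.
    """
    psi.require_normalized()
    S = psi.subspace
    na, nb = len(S.alpha_strings), len(S.beta_strings)
    w = np.abs(np.asarray(psi.coefficients).reshape(na, nb)) ** 2
    wa = w.sum(axis=1)
    wb = w.sum(axis=0)
    bits_a = np.array(
        [[(a >> p) & 1 for p in range(S.m)] for a in S.alpha_strings], dtype=float
    )
    bits_b = np.array(
        [[(b >> p) & 1 for p in range(S.m)] for b in S.beta_strings], dtype=float
    )
    return np.concatenate([wa @ bits_a, wb @ bits_b])


def variance(ham: ActiveSpaceHamiltonian, psi: CIVector) -> float:
    """Hamiltonian variance ΔH = <psi|H²|psi> − <psi|H|psi>² (Hartree²).

    Computed with the full, unprojected Hamiltonian action (support on S
    and all connected determinants); clipped at zero when within −1e-10.
    """
    psi.require_normalized()
    hpsi = apply_hamiltonian(ham, psi, mode="full")
    S = psi.subspace
    nb = len(S.beta_strings)
    c = psi.coefficients
    energy = 0.0
    for ia, a in enumerate(S.alpha_strings):
        for ib, b in enumerate(S.beta_strings):
            cj = c[ia * nb + ib]
            if cj != 0:
                energy += np.conj(cj) * hpsi.get((a, b), 0.0)
    energy = float(np.real(energy))
    h2 = float(sum(abs(amp) ** 2 for amp in hpsi.values()))
    dh = h2 - energy**2
    if dh < -1e-10:
        return dh  # genuinely negative: caller should treat as an error
    return max(dh, 0.0)


def _davidson(
    a_mat: sp.csr_matrix,
    diag: np.ndarray,
    tol: float,
    max_iter: int,
    max_subspace: int,
) -> tuple[float, np.ndarray]:
    d = a_mat.shape[0]
    if d == 1:
        return float(diag[0]), np.ones(1)
    start = np.zeros(d)
    start[int(np.argmin(diag))] = 1.0
    V = start[:, None]
    best_res = np.inf
    theta, x = float(diag.min()), start
    for _ in range(max_iter):
        AV = a_mat @ V
        T = V.T @ AV
        evals, evecs = np.linalg.eigh(T)
        theta, y = float(evals[0]), evecs[:, 0]
        x = V @ y
        r = AV @ y - theta * x
        res = float(np.linalg.norm(r))
        best_res = min(best_res, res)
        if res <= tol:
            return theta, x / np.linalg.norm(x)
        denom = diag - theta
        denom = np.where(np.abs(denom) < 1e-8, np.copysign(1e-8, denom), denom)
        t = r / denom
        # re-orthogonalize (twice for numerical safety)
        for _ in range(2):
            t -= V @ (V.T @ t)
        tnorm = np.linalg.norm(t)
        if tnorm < 1e-12:
            t = np.random.default_rng(0).normal(size=d)
            for _ in range(2):
                t -= V @ (V.T @ t)
            tnorm = np.linalg.norm(t)
        V = np.hstack([V, (t / tnorm)[:, None]])
        if V.shape[1] > max_subspace:
            V, _ = np.linalg.qr(x[:, None])
    raise ConvergenceError("Davidson did not converge", best_res)


def davidson_lowest(
    ham: ActiveSpaceHamiltonian,
    subspace: DeterminantSubspace,
    tol: float = 1e-8,
    max_iter: int = 300,
    max_subspace: int = 25,
    compute_variance: bool = True,
    dense_cutoff: int = 64,
) -> SubspaceResult:
    """Lowest eigenpair of the projected Hamiltonian H_S.

    The Davidson iteration uses a diagonal preconditioner, the
    lowest-diagonal determinant as start vector and a restarted search
    space; spaces of dimension up to ``dense_cutoff`` are diagonalized
    densely instead.  Occupation numbers are always populated; the
    (full-action) variance only when ``compute_variance`` is set.
    """
    a_mat = hamiltonian_matrix(ham, subspace)
    diag = a_mat.diagonal()
    if subspace.dimension <= dense_cutoff:
        evals, evecs = np.linalg.eigh(a_mat.toarray())
        energy, vec = float(evals[0]), evecs[:, 0]
    else:
        energy, vec = _davidson(a_mat, diag, tol, max_iter, max_subspace)
    if vec[int(np.argmax(np.abs(vec)))] < 0:
        vec = -vec
    state = CIVector(subspace, vec)
    occ = occupations(state)
    var = variance(ham, state) if compute_variance else None
    return SubspaceResult(energy, state, occ, var)


def casci_energy(
    ham: ActiveSpaceHamiltonian,
    tol: float = 1e-8,
    max_dimension: int = 2_000_000,
    compute_variance: bool = True,
) -> SubspaceResult:
    """Exact diagonalization over the complete determinant space (CASCI)."""
    d = cas_dimension(ham.m, ham.n_alpha, ham.n_beta)
    if d > max_dimension:
        raise CapacityError(d, max_dimension)
    S = DeterminantSubspace.full(ham.m, ham.n_alpha, ham.n_beta)
    return davidson_lowest(ham, S, tol=tol, compute_variance=compute_variance)
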