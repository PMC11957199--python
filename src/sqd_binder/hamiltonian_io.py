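"""Active-space Hamiltonians and molecular geometries.

The electronic Hamiltonian of an active space with M spatial orbitals is

    H = E0 + sum_{pr,s} h_pr a†_ps a_rs
           + 1/2 sum_{prqs,st} (pr|qs) a†_ps a†_qt a_st a_rs,

with one-electron integrals h_pr (symmetric), two-electron integrals
(pr|qs) in chemist notation with 8-fold permutational symmetry, and a
scalar E0 carrying nuclear repulsion plus inactive-orbital contributions.
This module reads and writes such Hamiltonians in the standard FCIDUMP
text format, handles XYZ geometries, generates seeded random test
Hamiltonians, and builds the rigid-translation geometry series used for
potential-energy-surface scans (including the 48.000 Å far-separated
"unbound" reference).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np

from .errors import EngineUnavailableError, FormatError, GeometryError


@dataclass
class ActiveSpaceHamiltonian:
    """Second-quantized Hamiltonian of an (N_alpha + N_beta, M) active space.

    Attributes
    ----------
    m : number of spatial orbitals M.
    n_alpha, n_beta : electrons per spin sector.
    e0 : scalar energy offset (Hartree).
    h : (M, M) symmetric one-electron integrals (Hartree).
    eri : (M, M, M, M) two-electron integrals (pr|qs), chemist notation,
        stored with all 8 symmetry-equivalent entries populated.
    """

    m: int
    n_alpha: int
    n_beta: int
    e0: float
    h: np.ndarray
    eri: np.ndarray

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one orbital")
        if not (0 <= self.n_alpha <= self.m and 0 <= self.n_beta <= self.m):
            raise ValueError("electron counts must satisfy 0 <= N_sigma <= M")
        self.h = np.asarray(self.h, dtype=float)
        self.eri = np.asarray(self.eri, dtype=float)
        if self.h.shape != (self.m, self.m):
            raise ValueError("h must be M x M")
        if self.eri.shape != (self.m,) * 4:
            raise ValueError("eri must be M x M x M x M")

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta

    def validate_symmetry(self, tol: float = 1e-10) -> None:
        """Raise if h is not symmetric or eri violates 8-fold symmetry."""
        if not np.allclose(self.h, self.h.T, atol=tol):
            raise ValueError("h is not symmetric")
        e = self.eri
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            if not np.allclose(e, e.transpose(perm), atol=tol):
                raise ValueError("eri violates 8-fold permutational symmetry")


@dataclass
class Geometry:
    """Molecular geometry: (element, x, y, z) tuples in Angstrom."""

    atoms: list[tuple[str, float, float, float]]
    metadata: str = ""

    def __post_init__(self) -> None:
        for el, *xyz in self.atoms:
            if not el:
                raise ValueError("element symbols must be non-empty")
            if not all(np.isfinite(c) for c in xyz):
                raise ValueError("coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)

    def distance(self, i: int, j: int) -> float:
        c = self.coords
        return float(np.linalg.norm(c[i] - c[j]))


@dataclass
class ActiveSpaceSpec:
    """Target active space selected from atomic-orbital labels.

    ``ao_labels`` follow the per-element shell convention, e.g.
    ``["O 2s", "O 2p", "H 1s"]`` for the (16e,12o) water-dimer space.
    """

    ao_labels: list[str]
    n_electrons: int
    n_orbitals: int

    def __post_init__(self) -> None:
        if self.n_orbitals < 1:
            raise ValueError("n_orbitals must be >= 1")
        if self.n_electrons > 2 * self.n_orbitals:
            raise ValueError("n_electrons must be <= 2 * n_orbitals")


def cas_dimension(m: int, n_alpha: int, n_beta: int) -> int:
    """Dimension C(M, N_alpha) * C(M, N_beta) of the full determinant space."""
    return comb(m, n_alpha) * comb(m, n_beta)


# ---------------------------------------------------------------------------
# FCIDUMP
# ---------------------------------------------------------------------------

_EIGHTFOLD = (
    (0, 1, 2, 3),
    (1, 0, 2, 3),
    (0, 1, 3, 2),
    (1, 0, 3, 2),
    (2, 3, 0, 1),
    (3, 2, 0, 1),
    (2, 3, 1, 0),
    (3, 2, 1, 0),
)


def _set_eri(eri: np.ndarray, p: int, r: int, q: int, s: int, val: float) -> None:
    idx = (p, r, q, s)
    for perm in _EIGHTFOLD:
        eri[tuple(idx[k] for k in perm)] = val


def read_fcidump(path: str | Path) -> ActiveSpaceHamiltonian:
    """Read an FCIDUMP file (1-based indices, chemist notation).

    N_alpha/N_beta derive from the NELEC and MS2 header fields; the core
    energy E0 is the record with all four indices zero.
    """
    text = Path(path).read_text()
    m = re.search(r"&FCI(.*?)(?:/|&END)", text, re.S | re.I)
    if m is None:
        raise FormatError(f"{path}: missing &FCI namelist header")
    header = m.group(1)

    def header_int(key: str) -> int:
        km = re.search(rf"{key}\s*=\s*(-?\d+)", header, re.I)
        if km is None:
            raise FormatError(f"{path}: header lacks {key}")
        return int(km.group(1))

    norb = header_int("NORB")
    nelec = header_int("NELEC")
    ms2 = header_int("MS2")
    if norb < 1:
        raise FormatError(f"{path}: NORB must be positive")
    if (nelec + ms2) % 2:
        raise FormatError(f"{path}: NELEC and MS2 have incompatible parity")
    n_alpha = (nelec + ms2) // 2
    n_beta = (nelec - ms2) // 2
    if not (0 <= n_beta <= n_alpha <= norb):
        raise FormatError(f"{path}: electron counts out of range")

    h = np.zeros((norb, norb))
    eri = np.zeros((norb,) * 4)
    e0 = 0.0
    body = text[text.index(m.group(0)) + len(m.group(0)):]
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FormatError(f"{path}: malformed record {line!r}")
        try:
            val = float(parts[0].replace("D", "E").replace("d", "e"))
            i, j, k, l = (int(x) for x in parts[1:])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed record {line!r}") from exc
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise FormatError(f"{path}: index {idx} outside [0, {norb}]")
        if i == j == k == l == 0:
            e0 = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise FormatError(f"{path}: bad one-electron record {line!r}")
            h[i - 1, j - 1] = val
            h[j - 1, i - 1] = val
        elif 0 in (i, j, k, l):
            raise FormatError(f"{path}: bad two-electron record {line!r}")
        else:
            _set_eri(eri, i - 1, j - 1, k - 1, l - 1, val)
    return ActiveSpaceHamiltonian(norb, n_alpha, n_beta, e0, h, eri)


def write_fcidump(ham: ActiveSpaceHamiltonian, path: str | Path) -> None:
    """Write an FCIDUMP file, one canonical record per 8-fold symmetry class.

    Entries below 1e-12 in magnitude are omitted (except E0, always written).
    """
    ham.validate_symmetry(tol=1e-9)
    m = ham.m
    lines = [
        f"&FCI NORB={m},NELEC={ham.n_electrons},MS2={ham.n_alpha - ham.n_beta},",
        " ORBSYM=" + ",".join(["1"] * m) + ",",
        " ISYM=1,",
        "/",
    ]

    def rec(val: float, i: int, j: int, k: int, l: int) -> str:
        return f"{val: .16E} {i:4d} {j:4d} {k:4d} {l:4d}"

    # canonical representative: i >= j, k >= l, (i,j) >= (k,l) lexicographically
    for i in range(m):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    val = ham.eri[i, j, k, l]
                    if abs(val) >= 1e-12:
                        lines.append(rec(val, i + 1, j + 1, k + 1, l + 1))
    for i in range(m):
        for j in range(i + 1):
            if abs(ham.h[i, j]) >= 1e-12:
                lines.append(rec(ham.h[i, j], i + 1, j + 1, 0, 0))
    lines.append(rec(ham.e0, 0, 0, 0, 0))
    Path(path).write_text("\n".join(lines) + "\n")


def random_hamiltonian(
    m: int, n_alpha: int, n_beta: int, seed: int, scale: float = 1.0
) -> ActiveSpaceHamiltonian:
    """Seeded random Hamiltonian with the correct integral symmetries.

    h is a symmetrized Gaussian matrix; eri is a Gaussian 4-tensor averaged
    over the 8 permutations. Deterministic for a fixed seed.
    """
    if m < 1 or not (0 <= n_alpha <= m and 0 <= n_beta <= m):
        raise ValueError("invalid orbital/electron counts")
    rng = np.random.default_rng(seed)
    h = rng.normal(scale=scale, size=(m, m))
    h = (h + h.T) / 2
    g = rng.normal(scale=scale, size=(m,) * 4)
    eri = np.zeros_like(g)
    for perm in _EIGHTFOLD:
        eri += g.transpose(perm)
    eri /= len(_EIGHTFOLD)
    e0 = float(rng.normal(scale=scale))
    return ActiveSpaceHamiltonian(m, n_alpha, n_beta, e0, h, eri)


def single_reference_hamiltonian(
    m: int,
    n_alpha: int,
    n_beta: int,
    seed: int,
    correlation: float = 0.25,
) -> ActiveSpaceHamiltonian:
    """Seeded toy Hamiltonian with a dominant reference determinant.

    Orbital energies are spread evenly over [-2, 1] Hartree and the
    random one-/two-body integrals are scaled down by ``correlation``,
    mimicking a weakly correlated (single-reference) molecule.  In this
    regime truncated-subspace energies depend nearly linearly on the
    Hamiltonian variance, the premise of zero-variance extrapolation.
    """
    base = random_hamiltonian(m, n_alpha, n_beta, seed=seed, scale=correlation)
    h = base.h * 0.3 + np.diag(np.linspace(-2.0, 1.0, m))
    return ActiveSpaceHamiltonian(m, n_alpha, n_beta, base.e0, h, base.eri * 0.4)


# ---------------------------------------------------------------------------
# XYZ geometries and PES generation
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path) -> Geometry:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: first line must be the atom count") from exc
    if len(lines) < natoms + 2:
        raise FormatError(f"{path}: expected {natoms} atom lines")
    atoms = []
    for line in lines[2 : natoms + 2]:
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom line {line!r}")
        atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    return Geometry(atoms, metadata=lines[1].strip())


def write_xyz(geom: Geometry, path: str | Path) -> None:
    lines = [str(len(geom.atoms)), geom.metadata]
    for el, x, y, z in geom.atoms:
        lines.append(f"{el:2s} {x: .10f} {y: .10f} {z: .10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def translate_monomer(
    geom: Geometry,
    monomer_b_atoms: set[int],
    anchor_a: int,
    anchor_b: int,
    target_distance: float,
) -> Geometry:
    """Rigidly translate monomer B along the anchor A -> anchor B axis.

    The anchor-atom separation becomes ``target_distance`` (Angstrom) while
    every intra-monomer distance is preserved exactly. Used to build
    one-dimensional PES grids and the 48.000 Å unbound reference of the
    supramolecular binding protocol.
    """
    b_set = set(monomer_b_atoms)
    if anchor_b not in b_set:
        raise ValueError("anchor_b must belong to monomer B")
    if anchor_a in b_set:
        raise ValueError("anchor_a must not belong to monomer B")
    coords = geom.coords
    axis = coords[anchor_b] - coords[anchor_a]
    current = float(np.linalg.norm(axis))
    if current <= 0.0:
        raise GeometryError("translation anchors are coincident")
    shift = (target_distance - current) * axis / current
    atoms = []
    for idx, (el, x, y, z) in enumerate(geom.atoms):
        if idx in b_set:
            x, y, z = (np.array([x, y, z]) + shift).tolist()
        atoms.append((el, x, y, z))
    meta = f"{geom.metadata} [anchor distance {target_distance:.3f} A]".strip()
    return Geometry(atoms, metadata=meta)


def pes_geometries(
    geom: Geometry,
    monomer_b_atoms: set[int],
    anchor_a: int,
    anchor_b: int,
    distances: list[float],
    unbound_distance: float = 48.0,
) -> tuple[list[tuple[float, Geometry]], Geometry]:
    """Geometry series for a binding curve plus the unbound reference.

    Returns ``([(distance, geometry), ...], unbound_geometry)`` with the
    grid sorted ascending; the unbound reference defaults to 48.000 Å.
    """
    grid = sorted(distances)
    series = [
        (d, translate_monomer(geom, monomer_b_atoms, anchor_a, anchor_b, d))
        for d in grid
    ]
    unbound = translate_monomer(
        geom, monomer_b_atoms, anchor_a, anchor_b, unbound_distance
    )
    return series, unbound


def prepare_active_space(
    geom: Geometry, spec: ActiveSpaceSpec, basis: str
) -> ActiveSpaceHamiltonian:
    """Mean-field + AVAS + integral transformation via an external engine.

    This is an integration boundary: the restricted Hartree-Fock solution,
    atomic valence active space (AVAS) projection onto ``spec.ao_labels``,
    and the transformation to active-space integrals are delegated to pyscf
    when it is installed. Without the engine this raises
    :class:`EngineUnavailableError`; every other entry point of the package
    operates from FCIDUMP files alone.
    """
    try:
        from pyscf import gto, scf, mcscf, ao2mo  # type: ignore
        from pyscf.mcscf import avas  # type: ignore
    except ImportError as exc:
        raise EngineUnavailableError(
            "prepare_active_space requires the pyscf electronic-structure "
            "engine, which is not installed; supply an FCIDUMP file instead"
        ) from exc

    mol = gto.M(
        atom=[(el, (x, y, z)) for el, x, y, z in geom.atoms],
        basis=basis,
        unit="Angstrom",
    )
    mf = scf.RHF(mol).run()
    norb, nelec, mo = avas.avas(mf, spec.ao_labels)
    if norb != spec.n_orbitals or nelec != spec.n_electrons:
        raise EngineUnavailableError(
            f"AVAS returned ({nelec}e,{norb}o), expected "
            f"({spec.n_electrons}e,{spec.n_orbitals}o); adjust ao_labels"
        )
    cas = mcscf.CASCI(mf, norb, nelec)
    h1, e0 = cas.get_h1eff(mo)
    eri = ao2mo.restore(1, cas.get_h2eff(mo), norb)
    n_alpha = (nelec + mol.spin) // 2
    n_beta = nelec - n_alpha
    return ActiveSpaceHamiltonian(norb, n_alpha, n_beta, float(e0), h1, eri)
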