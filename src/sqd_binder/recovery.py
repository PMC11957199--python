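"""Self-consistent configuration recovery.

Measurement noise produces configurations with incorrect electron
counts.  Recovery repairs each corrupted shot using an estimate of the
ground-state spin-orbital occupation numbers n_p(sigma): within each
spin sector, missing electrons are inserted at empty orbitals chosen
with probability proportional to n_p, and surplus electrons are removed
from occupied orbitals with probability proportional to 1 - n_p, one at
a time without replacement.  From the repaired pool, K batches are drawn
with replacement; each batch spans a Cartesian-product determinant
subspace S(b) = A x B (unique alpha strings times unique beta strings)
in which the Hamiltonian is diagonalized.  The lowest batch energy
min_b E(b) is the current ground-state estimate, and the occupations are
refreshed as the uniform average over the K batch eigenstates

    n_p(sigma) = (1/K) sum_b <psi(b)| n̂_p(sigma) |psi(b)>,

closing the self-consistency loop.  On noiseless samples recovery is the
identity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _bits
from .determinant_ci import (
    DeterminantSubspace,
    SubspaceResult,
    davidson_lowest,
)
from .errors import InitializationError
from .hamiltonian_io import ActiveSpaceHamiltonian
from .sampling import SampleSet, filter_correct_number


@dataclass
class OccupationEstimate:
    """Estimated spin-orbital occupations, length 2M (alpha block first).

    Entries are clipped to [0, 1]; per-spin sums need not equal the
    sector electron counts — this is an estimate, not an eigenstate
    property.
    """

    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.clip(np.asarray(self.n, dtype=float), 0.0, 1.0)
        if self.n.ndim != 1 or self.n.size % 2:
            raise ValueError("occupation vector must have 2M entries")

    @property
    def m(self) -> int:
        return self.n.size // 2


@dataclass
class RecoveryConfig:
    """Knobs of the recovery loop.

    k : number of batches per iteration.
    batch_size : shots per batch |chi~_b|.
    iterations : maximum recovery steps.
    energy_tol : early stop when |Delta min_b E(b)| falls below (Hartree).
    seed : master seed for recovery and batching randomness.
    solver_tol : Davidson residual threshold per batch diagonalization.
    compute_variance : populate per-batch Hamiltonian variances.
    """

    k: int = 10
    batch_size: int = 10_000
    iterations: int = 10
    energy_tol: float = 1e-6
    seed: int = 0
    solver_tol: float = 1e-8
    compute_variance: bool = True

    def __post_init__(self) -> None:
        if self.k < 1 or self.batch_size < 1 or self.iterations < 1:
            raise ValueError("k, batch_size and iterations must be >= 1")


@dataclass
class IterationRecord:
    """One recovery step: per-batch eigenpairs and the running estimate."""

    iteration: int
    results: list[SubspaceResult]
    e_min: float
    best_batch: int
    occupations: OccupationEstimate


@dataclass
class RecoveryResult:
    iterations: list[IterationRecord] = field(default_factory=list)

    @property
    def final(self) -> IterationRecord:
        return self.iterations[-1]

    @property
    def energy(self) -> float:
        return self.final.e_min

    @property
    def energy_history(self) -> list[float]:
        return [rec.e_min for rec in self.iterations]


def init_occupations(
    samples: SampleSet, n_alpha: int, n_beta: int
) -> OccupationEstimate:
    """Count-weighted mean occupation over correct-particle-number shots."""
    correct = filter_correct_number(samples, n_alpha, n_beta)
    if correct.shots == 0:
        raise InitializationError(
            "no measurement outcome has the correct particle number; "
            "increase the shot count or reduce the noise level"
        )
    m = samples.m
    acc = np.zeros(2 * m)
    for cfg, count in correct.counts.items():
        acc += count * np.array(
            [(cfg >> p) & 1 for p in range(2 * m)], dtype=float
        )
    return OccupationEstimate(acc / correct.shots)


def _recover_sector(
    mask: int, m: int, n_target: int, probs: np.ndarray, rng: np.random.Generator
) -> int:
    """Repair one spin sector to exactly ``n_target`` electrons."""
    current = _bits.popcount(mask)
    while current != n_target:
        if current < n_target:
            candidates = _bits.vir_list(mask, m)
            weights = probs[candidates]
        else:
            candidates = _bits.occ_list(mask, m)
            weights = 1.0 - probs[candidates]
        total = weights.sum()
        if total <= 0.0:
            weights = np.ones(len(candidates))  # degenerate: uniform fallback
            total = weights.sum()
        choice = candidates[rng.choice(len(candidates), p=weights / total)]
        mask ^= 1 << choice
        current = _bits.popcount(mask)
    return mask


def recover_configuration(
    config: int,
    n: OccupationEstimate,
    n_alpha: int,
    n_beta: int,
    rng: np.random.Generator,
) -> int:
    """Restore exact per-sector particle numbers to one configuration.

    Sectors are treated independently; a sector that already has the
    correct electron count is returned unchanged.
    """
    m = n.m
    alpha, beta = _bits.unpack(config, m)
    alpha = _recover_sector(alpha, m, n_alpha, n.n[:m], rng)
    beta = _recover_sector(beta, m, n_beta, n.n[m:], rng)
    return _bits.pack(alpha, beta, m)


def recover_samples(
    samples: SampleSet,
    n: OccupationEstimate,
    n_alpha: int,
    n_beta: int,
    rng: np.random.Generator,
) -> SampleSet:
    """Recover every shot independently; correct shots pass through."""
    m = samples.m
    out: dict[int, int] = {}
    for cfg, count in sorted(samples.counts.items()):
        a, b = _bits.unpack(cfg, m)
        if _bits.popcount(a) == n_alpha and _bits.popcount(b) == n_beta:
            out[cfg] = out.get(cfg, 0) + count
            continue
        for _ in range(count):
            fixed = recover_configuration(cfg, n, n_alpha, n_beta, rng)
            out[fixed] = out.get(fixed, 0) + 1
    return SampleSet(m, out)


def make_batches(
    samples: SampleSet, k: int, batch_size: int, rng: np.random.Generator
) -> list[SampleSet]:
    """K independent multinomial draws of ``batch_size`` shots from the pool."""
    if samples.shots == 0:
        raise ValueError("cannot batch an empty sample set")
    cfgs = samples.configurations()
    probs = np.array([samples.counts[int(c)] for c in cfgs], dtype=float)
    probs /= probs.sum()
    batches = []
    for _ in range(k):
        draws = rng.multinomial(batch_size, probs)
        batches.append(
            SampleSet(
                samples.m,
                {int(c): int(d) for c, d in zip(cfgs, draws) if d > 0},
            )
        )
    return batches


def build_subspace(
    batch: SampleSet, n_alpha: int, n_beta: int
) -> DeterminantSubspace:
    """Cartesian-product subspace spanned by a batch's half-strings.

    A is the set of unique alpha strings in the batch, B the unique beta
    strings; S(b) = A x B with dimension |A| * |B|.  All configurations
    must already carry the correct particle numbers.
    """
    m = batch.m
    alphas, betas = set(), set()
    for cfg in batch.counts:
        a, b = _bits.unpack(cfg, m)
        if _bits.popcount(a) != n_alpha or _bits.popcount(b) != n_beta:
            raise ValueError(
                "batch contains a configuration with wrong particle number; "
                "run configuration recovery first"
            )
        alphas.add(a)
        betas.add(b)
    return DeterminantSubspace(m, sorted(alphas), sorted(betas))


def recovery_loop(
    ham: ActiveSpaceHamiltonian,
    raw: SampleSet,
    config: RecoveryConfig,
) -> RecoveryResult:
    """Iterate recovery -> batching -> diagonalization -> occupation update.

    Raw shots are re-recovered from scratch each iteration with the
    current occupation estimate.  Stops after ``config.iterations`` steps
    or when min_b E(b) changes by less than ``config.energy_tol``.
    """
    na, nb = ham.n_alpha, ham.n_beta
    estimate = init_occupations(raw, na, nb)
    seeds = np.random.SeedSequence(config.seed).spawn(config.iterations)
    result = RecoveryResult()
    prev_energy = None
    for it, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        pool = recover_samples(raw, estimate, na, nb, rng)
        batches = make_batches(pool, config.k, config.batch_size, rng)
        results = []
        for batch in batches:
            subspace = build_subspace(batch, na, nb)
            results.append(
                davidson_lowest(
                    ham,
                    subspace,
                    tol=config.solver_tol,
                    compute_variance=config.compute_variance,
                )
            )
        energies = [r.energy for r in results]
        best = int(np.argmin(energies))
        e_min = energies[best]
        estimate = OccupationEstimate(
            np.mean([r.occupations for r in results], axis=0)
        )
        result.iterations.append(
            IterationRecord(it, results, e_min, best, estimate)
        )
        if prev_energy is not None and abs(e_min - prev_energy) < config.energy_tol:
            break
        prev_energy = e_min
    return result
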