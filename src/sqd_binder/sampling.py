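"""Synthetic measurement module.

Emulates computational-basis measurement of the ansatz state: shots are
drawn i.i.d. from |<x|Psi>|^2 over 2M-bit configurations, then corrupted
by independent per-bit flips with probability epsilon.  The bit flips
are the device-noise signature that matters to configuration recovery:
they break particle-number conservation, so the corrupted distribution
p~(x) places weight on configurations with incorrect electron counts.
Correlated hardware errors are deliberately not modeled.

Configurations pack the alpha occupation string in the low M bits and
the beta string in the high M bits; sample sets store multiplicities
(counts), never expanded per-shot lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _bits
from .determinant_ci import CIVector
from .errors import FormatError


@dataclass
class NoiseModel:
    """Uniform independent bit-flip noise with per-bit probability epsilon."""

    epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass
class SampleSet:
    """Multiset of 2M-bit configurations with multiplicities."""

    m: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        limit = 1 << (2 * self.m)
        for cfg, count in self.counts.items():
            if not 0 <= cfg < limit:
                raise ValueError(f"configuration {cfg} needs more than 2M bits")
            if count < 0:
                raise ValueError("counts must be non-negative")

    @property
    def shots(self) -> int:
        return sum(self.counts.values())

    def configurations(self) -> np.ndarray:
        """Distinct configurations, sorted ascending."""
        return np.array(sorted(self.counts), dtype=np.int64)

    def expanded(self) -> np.ndarray:
        """Per-shot configuration array (sorted by configuration)."""
        cfgs = self.configurations()
        reps = np.array([self.counts[int(c)] for c in cfgs])
        return np.repeat(cfgs, reps)

    @classmethod
    def from_array(cls, configs: np.ndarray, m: int) -> "SampleSet":
        values, counts = np.unique(np.asarray(configs, dtype=np.int64),
                                   return_counts=True)
        return cls(m, {int(v): int(c) for v, c in zip(values, counts)})


def sample_state(psi: CIVector, shots: int, seed: int) -> SampleSet:
    """Draw ``shots`` i.i.d. configurations with probability |<x|Psi>|^2."""
    if shots < 0:
        raise ValueError("shots must be non-negative")
    psi.require_normalized()
    S = psi.subspace
    m = S.m
    if shots == 0:
        return SampleSet(m, {})
    probs = np.abs(np.asarray(psi.coefficients)) ** 2
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, probs)
    nb = len(S.beta_strings)
    counts: dict[int, int] = {}
    for flat in np.nonzero(draws)[0]:
        a = S.alpha_strings[flat // nb]
        b = S.beta_strings[flat % nb]
        counts[_bits.pack(a, b, m)] = int(draws[flat])
    return SampleSet(m, counts)


def corrupt(samples: SampleSet, noise: NoiseModel) -> SampleSet:
    """Flip each bit of each shot independently with probability epsilon."""
    nbits = 2 * samples.m
    shots = samples.shots
    if shots == 0 or noise.epsilon == 0.0:
        return SampleSet(samples.m, dict(samples.counts))
    rng = np.random.default_rng(noise.seed)
    configs = samples.expanded()
    flips = rng.random((shots, nbits)) < noise.epsilon
    weights = (1 << np.arange(nbits, dtype=np.int64))
    flip_masks = flips @ weights
    return SampleSet.from_array(configs ^ flip_masks, samples.m)


def filter_correct_number(
    samples: SampleSet, n_alpha: int, n_beta: int
) -> SampleSet:
    """Keep only configurations with the target per-sector electron counts."""
    m = samples.m
    kept = {}
    for cfg, count in samples.counts.items():
        a, b = _bits.unpack(cfg, m)
        if _bits.popcount(a) == n_alpha and _bits.popcount(b) == n_beta:
            kept[cfg] = count
    return SampleSet(m, kept)


# ---------------------------------------------------------------------------
# serialization: "bitstring count" rows plus a JSON metadata header
# ---------------------------------------------------------------------------


def write_samples(
    samples: SampleSet, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a sample set as plain text.

    First line: ``# {json}`` with M, shots and any extra metadata
    (e.g. seed, epsilon).  Then one ``bitstring count`` row per distinct
    configuration — alpha block then beta block, orbital 1 leftmost —
    mirroring measurement-outcome dumps so hardware data can be ingested.
    """
    meta = {"M": samples.m, "shots": samples.shots}
    meta.update(metadata or {})
    lines = ["# " + json.dumps(meta, sort_keys=True)]
    for cfg in sorted(samples.counts):
        lines.append(f"{_bits.to_string(cfg, samples.m)} {samples.counts[cfg]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_samples(path: str | Path) -> tuple[SampleSet, dict]:
    """Inverse of :func:`write_samples`; returns (samples, metadata)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing JSON metadata header")
    try:
        meta = json.loads(lines[0][1:].strip())
        m = int(meta["M"])
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"{path}: malformed metadata header") from exc
    counts: dict[int, int] = {}
    for line in lines[1:]:
        line = line.strip()
        if not line:
            continue
        try:
            bitstring, count = line.split()
            cfg = _bits.from_string(bitstring)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed row {line!r}") from exc
        if len(bitstring) != 2 * m:
            raise FormatError(f"{path}: row has wrong bitstring length")
        counts[cfg] = counts.get(cfg, 0) + int(count)
    samples = SampleSet(m, counts)
    if "shots" in meta and samples.shots != meta["shots"]:
        raise FormatError(f"{path}: shot total disagrees with metadata")
    return samples, meta
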