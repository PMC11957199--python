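"""Bitmask helpers for determinant occupation strings.

A determinant over M spatial orbitals is a pair of integer masks
(alpha, beta); bit p (0-based) set means spatial orbital p+1 is occupied
in that spin sector.  Full 2M-bit configurations pack alpha in the low M
bits and beta in the high M bits.
"""

from __future__ import annotations

from itertools import combinations


def popcount(x: int) -> int:
    return int(x).bit_count()


def occ_list(mask: int, m: int) -> list[int]:
    """Indices of set bits below position ``m``, ascending."""
    return [p for p in range(m) if (mask >> p) & 1]


def vir_list(mask: int, m: int) -> list[int]:
    """Indices of clear bits below position ``m``, ascending."""
    return [p for p in range(m) if not (mask >> p) & 1]


def all_strings(m: int, n: int) -> list[int]:
    """All C(m, n) occupation masks with n of m bits set, sorted ascending."""
    out = [sum(1 << p for p in occ) for occ in combinations(range(m), n)]
    out.sort()
    return out


def pack(alpha: int, beta: int, m: int) -> int:
    return alpha | (beta << m)


def unpack(config: int, m: int) -> tuple[int, int]:
    return config & ((1 << m) - 1), config >> m


def to_string(config: int, m: int) -> str:
    """Plain-text form: alpha block then beta block, orbital 1 leftmost."""
    a, b = unpack(config, m)
    return "".join(str((a >> p) & 1) for p in range(m)) + "".join(
        str((b >> p) & 1) for p in range(m)
    )


def from_string(s: str) -> int:
    """Inverse of :func:`to_string`; length must be even (= 2M)."""
    if len(s) % 2:
        raise ValueError("configuration string length must be even (2M bits)")
    m = len(s) // 2
    a = sum((1 << p) for p in range(m) if s[p] == "1")
    b = sum((1 << p) for p in range(m) if s[m + p] == "1")
    return pack(a, b, m)


def annihilate(mask: int, p: int) -> tuple[int, int]:
    """Apply a_p to a single-sector mask; returns (new_mask, phase).

    Phase is (-1)^(number of occupied orbitals below p); phase 0 if bit empty.
    """
    if not (mask >> p) & 1:
        return 0, 0
    phase = -1 if popcount(mask & ((1 << p) - 1)) & 1 else 1
    return mask & ~(1 << p), phase


def create(mask: int, p: int) -> tuple[int, int]:
    """Apply a†_p to a single-sector mask; returns (new_mask, phase)."""
    if (mask >> p) & 1:
        return 0, 0
    phase = -1 if popcount(mask & ((1 << p) - 1)) & 1 else 1
    return mask | (1 << p), phase


def excitation_phase(mask: int, p: int, r: int) -> int:
    """Phase of a†_r a_p acting on ``mask`` (p occupied, r empty or r == p)."""
    if p == r:
        return 1
    m1, ph1 = annihilate(mask, p)
    m2, ph2 = create(m1, r)
    return ph1 * ph2
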