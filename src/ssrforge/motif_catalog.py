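"""Enumeration of the repeat-unit search space.

A microsatellite class is identified by a *primitive*, *rotation-canonical*
motif: primitive because a motif that is a whole-number power of a shorter
one (``ATAT`` = ``AT``×2) duplicates the shorter class, and rotation-canonical
because a tandem run reads as every cyclic rotation of its unit depending on
phase (``...AGAGAG...`` is both AG- and GA-repeats). The canonical
representative is the lexicographically smallest rotation.

Reverse-complement classes are deliberately *not* merged (AG and CT stay
distinct): per-strand reporting preserves the motif as it appears in the
input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from ssrforge.errors import ConfigError, DomainError

_ACGT = frozenset("ACGT")
MAX_MOTIF_LENGTH = 6


@dataclass(frozen=True, order=True)
class MotifClass:
    """A primitive repeat unit in rotation-canonical form."""

    unit: str

    @property
    def k(self) -> int:
        """Motif length in nt (the "k-mer" class)."""
        return len(self.unit)

    def __post_init__(self) -> None:
        if not (1 <= len(self.unit) <= MAX_MOTIF_LENGTH):
            raise DomainError(f"motif length must be 1..{MAX_MOTIF_LENGTH}: {self.unit!r}")
        if set(self.unit) - _ACGT:
            raise DomainError(f"motif must be over ACGT: {self.unit!r}")
        if not is_primitive(self.unit):
            raise DomainError(f"motif is not primitive: {self.unit!r}")
        if self.unit != canonical_rotation(self.unit):
            raise DomainError(f"motif is not rotation-canonical: {self.unit!r}")


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest cyclic rotation of ``unit``. Idempotent."""
    if not unit:
        raise DomainError("empty motif")
    if set(unit) - _ACGT:
        raise DomainError(f"motif must be over ACGT: {unit!r}")
    doubled = unit + unit
    return min(doubled[i:i + len(unit)] for i in range(len(unit)))


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number power of a shorter string."""
    if not unit:
        raise DomainError("empty motif")
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return False
    return True


def enumerate_motifs(k_min: int, k_max: int) -> List[MotifClass]:
    """All primitive rotation-canonical motif classes with k in [k_min, k_max].

    Deterministic order: by k, then lexicographic. Sizes for k = 1..5 are
    4, 6, 20, 60, 204 (Lyndon-word counts over a 4-letter alphabet).
    """
    if not (1 <= k_min <= k_max <= MAX_MOTIF_LENGTH):
        raise ConfigError(
            f"motif length bounds must satisfy 1 <= k_min <= k_max <= "
            f"{MAX_MOTIF_LENGTH}, got ({k_min}, {k_max})"
        )
    out: List[MotifClass] = []
    for k in range(k_min, k_max + 1):
        seen = set()
        for idx in range(4 ** k):
            unit = ""
            v = idx
            for _ in range(k):
                unit = "ACGT"[v & 3] + unit
                v >>= 2
            if not is_primitive(unit):
                continue
            canon = canonical_rotation(unit)
            if canon not in seen:
                seen.add(canon)
        out.extend(MotifClass(u) for u in sorted(seen))
    return out
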