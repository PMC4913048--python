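"""Flank-aware PCR primer-pair design for detected microsatellites.

A deterministic, exhaustive engine in the spirit of Primer3's default
behavior: every window of allowed length in the left flank is a forward
candidate and every window in the right flank (reverse-complemented) a
reverse candidate; candidates are filtered by hard constraints (size, Tm and
GC windows, mononucleotide runs, self-complementarity, no N), scored by a
weighted deviation from the optima, paired under product-size and
Tm-difference constraints, and ranked by total penalty. The amplified
product always contains the full repeat: primers sit wholly in the flanks.

Loci too close to a sequence end — a frequent situation in short shotgun
reads — cannot host a primer on both sides and are filtered out before
design by :func:`has_sufficient_flanks`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

from ssrforge.errors import ConfigError, FlankError, ValidationError
from ssrforge.sequence_io import SequenceRecord
from ssrforge.ssr_scanner import SSRLocus
from ssrforge.thermo import gc_fraction, melting_temperature

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard windows, soft optima and pairing rules for primer design.

    Defaults mirror Primer3's published defaults: 18/20/27 nt primers,
    57/60/63 °C, 20/50/80 %GC, max 5-base mononucleotide run, self-
    complementarity caps 8 (anywhere) and 3 (3'-anchored), pair Tm
    difference <= 5 °C, 100-300 bp products, 50 mM monovalent salt and
    50 nM oligo concentration.
    """

    size_min: int = 18
    size_opt: int = 20
    size_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 20.0
    gc_opt: float = 50.0
    gc_max: float = 80.0
    max_poly_x: int = 5
    max_self_any: int = 8
    max_self_end: int = 3
    max_pair_tm_diff: float = 5.0
    product_min: int = 100
    product_max: int = 300
    monovalent_mM: float = 50.0
    oligo_nM: float = 50.0
    max_pairs_returned: int = 5
    weight_size: float = 1.0
    weight_tm: float = 1.0
    weight_gc: float = 0.1

    def __post_init__(self) -> None:
        for name in ("size", "tm", "gc"):
            lo = getattr(self, f"{name}_min")
            opt = getattr(self, f"{name}_opt")
            hi = getattr(self, f"{name}_max")
            if not (lo <= opt <= hi):
                raise ConfigError(
                    f"{name} triple must satisfy min <= opt <= max, "
                    f"got {lo}/{opt}/{hi}"
                )
        if self.product_min < 2 * self.size_min:
            raise ConfigError(
                f"product_min ({self.product_min}) must be >= 2 x size_min "
                f"({2 * self.size_min})"
            )
        positives = ("size_min", "max_poly_x", "product_min", "product_max",
                     "monovalent_mM", "oligo_nM", "max_pairs_returned")
        for name in positives:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.product_max < self.product_min:
            raise ConfigError("product_max must be >= product_min")


@dataclass(frozen=True)
class PrimerCandidate:
    """One oligo with its position and quality metrics.

    ``start``/``end`` are 1-based inclusive on the forward strand; for a
    reverse candidate ``oligo`` is the reverse complement of that window
    (written 5'→3' on the reverse strand, standard PCR convention).
    """

    seq_id: str
    strand: str                 # "forward" | "reverse"
    start: int
    end: int
    oligo: str
    tm: float
    gc_pct: float
    self_any: int
    self_end: int
    penalty: float

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.end - self.start + 1 != len(self.oligo):
            raise ValidationError("candidate span does not match oligo length")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair amplifying one SSR locus."""

    left: PrimerCandidate
    right: PrimerCandidate
    product_size: int
    pair_penalty: float
    target: SSRLocus

    def __post_init__(self) -> None:
        if self.product_size != self.right.end - self.left.start + 1:
            raise ValidationError("product_size inconsistent with primer positions")
        if not (self.left.end < self.target.start and
                self.right.start > self.target.end):
            raise ValidationError("primers must sit wholly in the flanks")


def has_sufficient_flanks(
    locus: SSRLocus, seq_length: int, constraints: Optional[PrimerConstraints] = None
) -> bool:
    """Can a conforming primer pair exist around this locus at all?

    True iff both flanks are at least ``size_min`` bp and the repeat plus
    two minimum-size primers fits inside ``product_max``.
    """
    if constraints is None:
        constraints = PrimerConstraints()
    if locus.start < 1 or locus.end > seq_length:
        raise ValidationError(
            f"locus {locus.start}-{locus.end} outside sequence of {seq_length} bp"
        )
    left_flank = locus.start - 1
    right_flank = seq_length - locus.end
    if left_flank < constraints.size_min or right_flank < constraints.size_min:
        return False
    return locus.length + 2 * constraints.size_min <= constraints.product_max


def self_complementarity(oligo: str) -> Tuple[int, int]:
    """Ungapped self-annealing scores (self_any, self_end).

    The oligo is slid against its own reversed copy at every offset; within
    the overlap each Watson-Crick pair scores +1 and each non-pairing
    juxtaposition −1 (so a fully complementary palindrome of length n scores
    n, while an unpairable homopolymer scores 0), and the per-offset scores
    are maximized. ``self_end`` restricts the maximum to alignments that
    involve the 3'-terminal base, flagging primer-dimer-prone 3' ends.
    """
    n = len(oligo)
    rev = oligo[::-1]
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    self_any = 0
    self_end = 0
    for offset in range(-(n - 1), n):
        score = 0
        covers_3prime = False
        for i in range(n):
            j = i + offset
            if 0 <= j < n:
                score += 1 if pair[oligo[i]] == rev[j] else -1
                if i == n - 1:
                    covers_3prime = True
        score = max(score, 0)
        self_any = max(self_any, score)
        if covers_3prime:
            self_end = max(self_end, score)
    return self_any, self_end


def max_mononucleotide_run(oligo: str) -> int:
    best = run = 1
    for a, b in zip(oligo, oligo[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if oligo else 0


def candidate_penalty(candidate: PrimerCandidate,
                      constraints: PrimerConstraints) -> float:
    """Weighted deviation of (length, Tm, GC) from their optima."""
    return (
        constraints.weight_size * abs(len(candidate.oligo) - constraints.size_opt)
        + constraints.weight_tm * abs(candidate.tm - constraints.tm_opt)
        + constraints.weight_gc * abs(candidate.gc_pct - constraints.gc_opt)
    )


def _make_candidate(
    seq_id: str, strand: str, start1: int, end1: int, oligo: str,
    c: PrimerConstraints,
) -> Optional[PrimerCandidate]:
    """Apply hard constraints; return a scored candidate or None."""
    if "N" in oligo:
        return None
    if max_mononucleotide_run(oligo) > c.max_poly_x:
        return None
    gc = gc_fraction(oligo)
    if not (c.gc_min <= gc <= c.gc_max):
        return None
    tm = melting_temperature(oligo, c.monovalent_mM, c.oligo_nM)
    if not (c.tm_min <= tm <= c.tm_max):
        return None
    s_any, s_end = self_complementarity(oligo)
    if s_any > c.max_self_any or s_end > c.max_self_end:
        return None
    cand = PrimerCandidate(
        seq_id=seq_id, strand=strand, start=start1, end=end1, oligo=oligo,
        tm=tm, gc_pct=gc, self_any=s_any, self_end=s_end, penalty=0.0,
    )
    return replace(cand, penalty=candidate_penalty(cand, c))


def enumerate_forward_candidates(
    record: SequenceRecord, locus: SSRLocus, c: PrimerConstraints
) -> List[PrimerCandidate]:
    """All passing forward candidates in the left flank of ``locus``.

    Restricted to starts from which a product within ``product_max`` is
    geometrically possible.
    """
    out: List[PrimerCandidate] = []
    # smallest achievable right primer end (1-based) is locus.end + size_min
    min_left_start = max(1, locus.end + c.size_min - c.product_max + 1)
    for start1 in range(min_left_start, locus.start):
        for size in range(c.size_min, c.size_max + 1):
            end1 = start1 + size - 1
            if end1 >= locus.start:
                break
            oligo = record.seq[start1 - 1:end1]
            cand = _make_candidate(record.id, "forward", start1, end1, oligo, c)
            if cand is not None:
                out.append(cand)
    return out


def enumerate_reverse_candidates(
    record: SequenceRecord, locus: SSRLocus, c: PrimerConstraints
) -> List[PrimerCandidate]:
    """All passing reverse candidates in the right flank of ``locus``."""
    out: List[PrimerCandidate] = []
    max_right_end = min(len(record.seq),
                        locus.start - c.size_min + c.product_max - 1)
    for end1 in range(locus.end + c.size_min, max_right_end + 1):
        for size in range(c.size_min, c.size_max + 1):
            start1 = end1 - size + 1
            if start1 <= locus.end:
                break
            oligo = reverse_complement(record.seq[start1 - 1:end1])
            cand = _make_candidate(record.id, "reverse", start1, end1, oligo, c)
            if cand is not None:
                out.append(cand)
    return out


def design_primer_pairs(
    record: SequenceRecord,
    locus: SSRLocus,
    constraints: Optional[PrimerConstraints] = None,
) -> List[PrimerPair]:
    """Ranked primer pairs for one locus (best first, at most
    ``max_pairs_returned``); empty when no pair satisfies every constraint.

    Raises
    ------
    FlankError
        If the locus fails :func:`has_sufficient_flanks` — callers are
        expected to filter such loci out beforehand.
    """
    c = constraints if constraints is not None else PrimerConstraints()
    if not has_sufficient_flanks(locus, record.length, c):
        raise FlankError(
            f"locus {locus.seq_id}:{locus.start}-{locus.end} lacks usable flanks"
        )
    lefts = enumerate_forward_candidates(record, locus, c)
    rights = enumerate_reverse_candidates(record, locus, c)

    pairs: List[PrimerPair] = []
    for left in lefts:
        for right in rights:
            product = right.end - left.start + 1
            if not (c.product_min <= product <= c.product_max):
                continue
            tm_diff = abs(left.tm - right.tm)
            if tm_diff > c.max_pair_tm_diff:
                continue
            pairs.append(PrimerPair(
                left=left, right=right, product_size=product,
                pair_penalty=left.penalty + right.penalty + tm_diff,
                target=locus,
            ))
    pairs.sort(key=lambda p: (p.pair_penalty, p.product_size, p.left.start))
    return pairs[: c.max_pairs_returned]
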