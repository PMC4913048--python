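"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's algorithms: the motif enumerator
walks every string with itertools, the repeat enumerator extends copy
counts position by position, the overlap filter is a separate greedy pass,
and the primer-pair oracle enumerates every window with no pruning.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

from ssrforge.primer_design import (
    PrimerConstraints,
    max_mononucleotide_run,
    reverse_complement,
    self_complementarity,
)
from ssrforge.thermo import gc_fraction, melting_temperature

Locus = Tuple[str, int, int, int, int]  # (canonical motif, repeats, length, start, end)


def bf_rotations(s: str) -> List[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def bf_is_primitive(s: str) -> bool:
    # classic doubling trick: s is a power of a shorter string iff it occurs
    # inside (s+s) at an offset other than 0 and len(s)
    return (s + s).find(s, 1) == len(s)


def bf_enumerate_motifs(k_min: int, k_max: int) -> List[str]:
    out = []
    for k in range(k_min, k_max + 1):
        seen = set()
        for tup in itertools.product("ACGT", repeat=k):
            s = "".join(tup)
            if bf_is_primitive(s):
                seen.add(min(bf_rotations(s)))
        out.extend(sorted(seen))
    return out


def bf_find_runs(
    seq: str,
    thresholds: Dict[int, int],
    masked_disallowed: Optional[set] = None,
) -> List[Locus]:
    """Maximal perfect tandem repeats by per-position copy extension.

    For each start and motif length, count whole tandem copies; keep the
    locus when the start is left-maximal (shifting one base left would not
    continue the same periodic run), the unit is primitive, and the total
    length meets the class threshold. 1-based inclusive coordinates.
    """
    n = len(seq)
    bad = masked_disallowed or set()

    def usable(i: int, j: int) -> bool:
        return all(seq[x] != "N" and x not in bad for x in range(i, j))

    loci: List[Locus] = []
    for k in sorted(thresholds):
        for i in range(n - 2 * k + 1):
            unit = seq[i:i + k]
            if "N" in unit or not usable(i, i + k) or not bf_is_primitive(unit):
                continue
            c = 1
            while (seq[i + c * k:i + (c + 1) * k] == unit
                   and usable(i + c * k, i + (c + 1) * k)):
                c += 1
            if c < 2:
                continue
            # left-maximal: the base before i must not continue the run
            if i > 0 and seq[i - 1] == seq[i - 1 + k] \
                    and seq[i - 1] != "N" and (i - 1) not in bad \
                    and (i - 1 + k) not in bad:
                continue
            length = c * k
            if length < thresholds[k]:
                continue
            loci.append((min(bf_rotations(unit)), c, length, i + 1, i + length))
    loci.sort(key=lambda l: (l[3], len(l[0])))
    return loci


def bf_resolve_overlaps(loci: Sequence[Locus]) -> List[Locus]:
    """Independent greedy pass: longest first, leftmost, shortest motif."""
    order = sorted(loci, key=lambda l: (-l[2], l[3], len(l[0])))
    taken: List[Locus] = []
    for cand in order:
        if all(cand[4] < t[3] or cand[3] > t[4] for t in taken):
            taken.append(cand)
    return sorted(taken, key=lambda l: l[3])


def bf_scan(seq: str, thresholds: Dict[int, int]) -> List[Locus]:
    return bf_resolve_overlaps(bf_find_runs(seq, thresholds))


def bf_best_pair(
    seq: str, locus_start: int, locus_end: int, c: PrimerConstraints
) -> Optional[Tuple[int, int, int, int, float]]:
    """Best primer pair by unpruned exhaustive enumeration.

    Returns (left_start, left_end, right_start, right_end, pair_penalty),
    1-based, or None when nothing qualifies. Ranking: penalty, then product
    size, then leftmost left primer.
    """
    n = len(seq)

    def metrics(oligo: str):
        if "N" in oligo or max_mononucleotide_run(oligo) > c.max_poly_x:
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
        penalty = (c.weight_size * abs(len(oligo) - c.size_opt)
                   + c.weight_tm * abs(tm - c.tm_opt)
                   + c.weight_gc * abs(gc - c.gc_opt))
        return tm, penalty

    lefts = []
    for s1 in range(1, locus_start):
        for size in range(c.size_min, c.size_max + 1):
            e1 = s1 + size - 1
            if e1 >= locus_start:
                continue
            m = metrics(seq[s1 - 1:e1])
            if m:
                lefts.append((s1, e1, m[0], m[1]))
    rights = []
    for e1 in range(locus_end + 1, n + 1):
        for size in range(c.size_min, c.size_max + 1):
            s1 = e1 - size + 1
            if s1 <= locus_end:
                continue
            m = metrics(reverse_complement(seq[s1 - 1:e1]))
            if m:
                rights.append((s1, e1, m[0], m[1]))

    best = None
    for ls, le, ltm, lp in lefts:
        for rs, re, rtm, rp in rights:
            product = re - ls + 1
            if not (c.product_min <= product <= c.product_max):
                continue
            diff = abs(ltm - rtm)
            if diff > c.max_pair_tm_diff:
                continue
            key = (lp + rp + diff, product, ls)
            if best is None or key < best[0]:
                best = (key, (ls, le, rs, re, lp + rp + diff))
    return best[1] if best else None
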