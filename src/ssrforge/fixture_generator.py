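"""Synthetic multi-FASTA inputs with a known truth table of planted repeats.

Emulates the shape of single-pass genomic shotgun reads: i.i.d. background
nucleotides at a configurable GC content (defaults to the ~44.6% GC of a
broad-snouted caiman partial-genome survey, a typical vertebrate value),
with perfect and deliberately interrupted (imperfect) microsatellites
planted at known coordinates. Backgrounds can be rejection-sampled until
they contain no reportable SSR of their own, so that the planted truth
table is exactly the expected scanner output.

The generator guards plant boundaries: the base on either side of a planted
run is adjusted so the tandem periodicity cannot leak into the background,
and each finished sequence is verified against the scanner before being
accepted — a fixture whose truth table disagrees with its own content is a
bug, not a test case.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from ssrforge.errors import GenerationError, ValidationError
from ssrforge.motif_catalog import canonical_rotation, enumerate_motifs
from ssrforge.sequence_io import SequenceRecord, write_fasta
from ssrforge.ssr_scanner import (
    ScanConfig, SSRLocus, find_perfect_runs, resolve_overlaps,
)

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42
DEFAULT_GUARD_GAP = 30
DEFAULT_GC_TARGET = 44.65


@dataclass(frozen=True)
class PlantSpec:
    """A request to plant one repeat: motif, copy number, 1-based start."""

    motif: str
    repeats: int
    start: int
    kind: str = "perfect"           # "perfect" | "imperfect"

    @property
    def length(self) -> int:
        return self.repeats * len(self.motif)

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class PlantedTruth:
    """Where and what was actually planted (the test oracle record)."""

    seq_id: str
    motif: str                      # rotation-canonical unit
    repeats: int
    start: int                      # 1-based inclusive
    end: int
    kind: str
    interruptions: Tuple[Tuple[int, str], ...] = field(default=())
    # interruptions: (0-based offset within the planted interval, new base)


def generate_background(
    length: int,
    gc_target: float = DEFAULT_GC_TARGET,
    seed: int = DEFAULT_SEED,
    forbid_ssrs: bool = False,
    config: Optional[ScanConfig] = None,
    max_retries: int = 200,
) -> str:
    """Random nucleotide string at the requested GC content.

    With ``forbid_ssrs`` the draw is rejected until the scanner (default
    thresholds) finds nothing in it; for length >= 1 kb the realized GC is
    additionally held within ~3 points of the target.
    """
    if length <= 0:
        raise GenerationError("background length must be positive")
    if not (0.0 <= gc_target <= 100.0):
        raise GenerationError(f"gc_target must be in [0, 100], got {gc_target}")
    if config is None:
        config = ScanConfig()
    catalog = enumerate_motifs(min(config.k_values), max(config.k_values))
    rng = random.Random(seed)
    p_gc = gc_target / 100.0
    weights = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]

    for _ in range(max_retries):
        seq = "".join(rng.choices("ACGT", weights=weights, k=length))
        if length >= 1000:
            gc = 100.0 * sum(1 for c in seq if c in "GC") / length
            if abs(gc - gc_target) > 2.5:
                continue
        if forbid_ssrs:
            rec = SequenceRecord(id="bg", description="", seq=seq)
            if find_perfect_runs(rec, catalog, config):
                continue
        return seq
    raise GenerationError(
        f"could not generate a conforming background of {length} bp "
        f"within {max_retries} attempts"
    )


def _split_offsets(total_len: int, k: int, threshold: int,
                   rng: random.Random) -> List[int]:
    """Interruption offsets so every clean segment stays below threshold.

    A clean segment of L bases of a period-k pattern contains floor(L/k)
    whole copies, i.e. floor(L/k)*k reportable bp; all segments must end up
    strictly below the class threshold.
    """
    offsets: List[int] = []
    segments = [(0, total_len)]     # half-open offsets within the plant
    while segments:
        start, end = segments.pop()
        seg_len = end - start
        if (seg_len // k) * k < threshold:
            continue
        mid = start + seg_len // 2 + rng.randint(-min(2, seg_len // 4),
                                                 min(2, seg_len // 4))
        mid = min(max(mid, start), end - 1)
        offsets.append(mid)
        segments.append((start, mid))
        segments.append((mid + 1, end))
    return sorted(offsets)


def _other_base(rng: random.Random, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return rng.choice(choices)


def plant_ssrs(
    background: str,
    specs: Sequence[PlantSpec],
    seed: int = DEFAULT_SEED,
    seq_id: str = "synthetic",
    config: Optional[ScanConfig] = None,
    guard_gap: int = DEFAULT_GUARD_GAP,
) -> Tuple[SequenceRecord, List[PlantedTruth]]:
    """Overwrite stretches of ``background`` with the requested repeats.

    Perfect plants become exactly ``motif × repeats``; imperfect plants are
    point-interrupted so that no clean sub-run reaches its class threshold.
    Planted intervals must be separated by at least ``guard_gap`` bases and
    lie at least ``guard_gap`` from either end.
    """
    if config is None:
        config = ScanConfig()
    rng = random.Random(seed)
    n = len(background)
    ordered = sorted(specs, key=lambda s: s.start)
    prev_end = 0
    for spec in ordered:
        if spec.start - 1 < guard_gap or spec.end > n - guard_gap:
            raise ValidationError(
                f"plant {spec.motif}x{spec.repeats}@{spec.start} violates the "
                f"{guard_gap} bp guard gap from the sequence ends"
            )
        if prev_end and spec.start - prev_end - 1 < guard_gap:
            raise ValidationError(
                f"plants at {prev_end} and {spec.start} closer than "
                f"guard gap {guard_gap}"
            )
        if spec.repeats < 2:
            raise ValidationError("planted repeats must have >= 2 copies")
        prev_end = spec.end

    chars = list(background)
    truths: List[PlantedTruth] = []
    for spec in ordered:
        k = len(spec.motif)
        s0 = spec.start - 1                     # 0-based
        e0 = spec.end - 1
        planted = spec.motif * spec.repeats
        chars[s0:e0 + 1] = list(planted)

        interruptions: Tuple[Tuple[int, str], ...] = ()
        if spec.kind == "imperfect":
            offs = _split_offsets(spec.length, k, config.threshold_for(k), rng)
            ints = []
            for off in offs:
                pos = s0 + off
                new = _other_base(rng, chars[pos],
                                  chars[pos - 1], chars[pos + 1])
                chars[pos] = new
                ints.append((off, new))
            interruptions = tuple(ints)
        elif spec.kind != "perfect":
            raise ValidationError(f"unknown plant kind {spec.kind!r}")

        # stop the periodicity from leaking into the background on either side
        left = s0 - 1
        if chars[left] == chars[left + k]:
            chars[left] = _other_base(rng, chars[left + k], chars[left - 1])
        right = e0 + 1
        if chars[right] == chars[right - k]:
            chars[right] = _other_base(rng, chars[right - k],
                                       chars[right + 1] if right + 1 < n else "")

        truths.append(PlantedTruth(
            seq_id=seq_id, motif=canonical_rotation(spec.motif),
            repeats=spec.repeats, start=spec.start, end=spec.end,
            kind=spec.kind, interruptions=interruptions,
        ))

    record = SequenceRecord(id=seq_id, description="synthetic fixture",
                            seq="".join(chars))
    return record, truths


def _random_specs(
    seq_length: int,
    n_perfect: int,
    n_imperfect: int,
    rng: random.Random,
    config: ScanConfig,
    guard_gap: int,
) -> List[PlantSpec]:
    catalog = enumerate_motifs(min(config.k_values), max(config.k_values))
    by_k: dict = {}
    for m in catalog:
        by_k.setdefault(m.k, []).append(m.unit)
    kinds = ["perfect"] * n_perfect + ["imperfect"] * n_imperfect
    rng.shuffle(kinds)
    specs: List[PlantSpec] = []
    cursor = guard_gap + 1
    for kind in kinds:
        # draw the class size k uniformly, then a motif within it, so the
        # planted spectrum is not dominated by the many pentamer classes
        k = rng.choice(sorted(by_k))
        motif = rng.choice(by_k[k])
        threshold = config.threshold_for(k)
        min_rep = max(2, -(-threshold // k))          # ceil
        repeats = rng.randint(min_rep, min_rep + 3)
        if kind == "imperfect":                       # long enough to split
            repeats = max(repeats, min_rep + 2)
        start = cursor + rng.randint(0, guard_gap)
        spec = PlantSpec(motif=motif, repeats=repeats, start=start, kind=kind)
        if spec.end > seq_length - guard_gap:
            break
        specs.append(spec)
        cursor = spec.end + guard_gap + 1
    return specs


def make_fixture(
    n_sequences: int = 10,
    seq_length: int = 1500,
    n_perfect_per_seq: int = 5,
    n_imperfect_per_seq: int = 2,
    gc_target: float = DEFAULT_GC_TARGET,
    seed: int = DEFAULT_SEED,
    config: Optional[ScanConfig] = None,
    guard_gap: int = DEFAULT_GUARD_GAP,
    out_fasta: Union[str, Path, None] = None,
    out_truth: Union[str, Path, None] = None,
    max_retries: int = 50,
) -> Tuple[List[SequenceRecord], List[PlantedTruth]]:
    """A multi-record fixture on SSR-free background, with its truth table.

    Every accepted sequence is verified: the scanner's overlap-resolved
    output must coincide exactly with the perfect-kind truth rows (and find
    nothing at imperfect plants); a sequence failing verification is
    redrawn. Optionally writes FASTA and a tab-separated truth table.
    """
    if config is None:
        config = ScanConfig()
    catalog = enumerate_motifs(min(config.k_values), max(config.k_values))
    records: List[SequenceRecord] = []
    truths: List[PlantedTruth] = []
    master = random.Random(seed)

    for i in range(n_sequences):
        seq_id = f"synth_{i + 1:03d}"
        for attempt in range(max_retries):
            sub = master.randrange(2 ** 31)
            try:
                bg = generate_background(seq_length, gc_target, sub,
                                         forbid_ssrs=True, config=config)
                rng = random.Random(sub + 1)
                specs = _random_specs(seq_length, n_perfect_per_seq,
                                      n_imperfect_per_seq, rng, config,
                                      guard_gap)
                record, truth = plant_ssrs(bg, specs, seed=sub + 2,
                                           seq_id=seq_id, config=config,
                                           guard_gap=guard_gap)
            except (ValidationError, GenerationError):
                continue
            expected = {
                (t.seq_id, t.motif, t.repeats, t.start, t.end)
                for t in truth if t.kind == "perfect"
            }
            found = {
                (l.seq_id, l.motif, l.repeats, l.start, l.end)
                for l in resolve_overlaps(
                    find_perfect_runs(record, catalog, config))
            }
            if expected == found:
                records.append(record)
                truths.extend(truth)
                break
        else:
            raise GenerationError(
                f"could not build a verified fixture sequence {seq_id} "
                f"within {max_retries} attempts"
            )

    if out_fasta is not None:
        write_fasta(records, out_fasta)
    if out_truth is not None:
        write_truth_table(truths, out_truth)
    logger.info("fixture: %d sequence(s), %d planted repeat(s)",
                len(records), len(truths))
    return records, truths


def write_truth_table(truths: Sequence[PlantedTruth],
                      path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        out.write("seq_id\tmotif\trepeats\tstart\tend\tkind\tinterruptions\n")
        for t in truths:
            ints = ";".join(f"{off}:{base}" for off, base in t.interruptions)
            out.write(f"{t.seq_id}\t{t.motif}\t{t.repeats}\t{t.start}\t"
                      f"{t.end}\t{t.kind}\t{ints}\n")
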