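"""Detection of maximal perfect tandem repeats (microsatellites).

The scanner finds, for every motif class in the catalog, every *maximal
periodic run* in a sequence: the longest stretch over which ``s[x] ==
s[x - k]`` holds. A locus is the whole-copy prefix of such a run — repeats
= floor(run / k) tandem copies anchored at the run start — so the reported
interval is always an exact concatenation of identical copies (a *perfect*
repeat; interrupted/imperfect repeats are discarded, they merely split a
region into sub-runs that usually fall below threshold). Runs never span an
N, and by default soft-masked bases are scanned like any other.

Per-class minimum total lengths filter out very short repeats. The
homopolymer (k=1) default of 9 bp encodes the "strictly greater than 8 bp"
rule; the k>=2 defaults follow common SSR-survey practice and are
config-overridable.

When two surviving loci overlap, only the longer one is reported (ties:
leftmost start, then shorter motif).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from ssrforge.errors import ConfigError, ValidationError
from ssrforge.motif_catalog import MotifClass, canonical_rotation, enumerate_motifs, is_primitive
from ssrforge.sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

#: minimum SSR length in bp per motif length k; k=1 encodes the >8 bp rule
DEFAULT_MIN_LENGTHS: Dict[int, int] = {1: 9, 2: 10, 3: 12, 4: 12, 5: 15}


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect tandem repeat.

    Coordinates are 1-based inclusive on the input sequence. ``motif`` is the
    rotation-canonical unit; the physical run may start at any phase of it.
    """

    seq_id: str
    motif: str
    repeats: int
    length: int
    start: int
    end: int

    @property
    def k(self) -> int:
        return len(self.motif)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.length:
            raise ValidationError(
                f"{self.seq_id}:{self.start}-{self.end}: span != length {self.length}"
            )
        if self.length != self.repeats * self.k:
            raise ValidationError(
                f"{self.seq_id}:{self.start}-{self.end}: length {self.length} != "
                f"{self.repeats} x |{self.motif}|"
            )
        if self.repeats < 2:
            raise ValidationError("a tandem repeat needs at least 2 copies")

    def overlaps(self, other: "SSRLocus") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds controlling which repeats are reported."""

    min_total_length_by_k: Dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_LENGTHS)
    )
    scan_masked: bool = True

    def __post_init__(self) -> None:
        for k, min_len in self.min_total_length_by_k.items():
            if min_len < 2 * k:
                raise ConfigError(
                    f"minimum length for k={k} must be >= {2 * k} "
                    f"(two full copies), got {min_len}"
                )

    def threshold_for(self, k: int) -> int:
        try:
            return self.min_total_length_by_k[k]
        except KeyError:
            raise ConfigError(f"no minimum-length threshold configured for k={k}")

    @property
    def k_values(self) -> List[int]:
        return sorted(self.min_total_length_by_k)


def _validity_mask(record: SequenceRecord, scan_masked: bool) -> np.ndarray:
    a = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8)
    valid = a != ord("N")
    if not scan_masked:
        for s, e in record.masked_runs:
            valid[s:e] = False
    return valid


def find_perfect_runs(
    record: SequenceRecord,
    catalog: Sequence[MotifClass],
    config: Optional[ScanConfig] = None,
) -> List[SSRLocus]:
    """All maximal perfect tandem repeats of catalog motifs in one record.

    Returns loci sorted by start (overlaps not yet resolved). Each physical
    run is reported once, under the canonical rotation of its unit.
    """
    if config is None:
        config = ScanConfig()
    if not catalog:
        raise ConfigError("motif catalog is empty")
    catalog_units = {m.unit for m in catalog}
    ks = sorted({m.k for m in catalog})

    seq = record.seq
    n = len(seq)
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = _validity_mask(record, config.scan_masked)

    loci: List[SSRLocus] = []
    for k in ks:
        if n < 2 * k:
            continue
        # m[x] is True when position x repeats k bases later and both are scannable
        m = (a[:-k] == a[k:]) & valid[:-k] & valid[k:]
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([False], m, [False])).astype(np.int8)))
        for b, e in zip(edges[0::2], edges[1::2]):
            match_len = int(e - b)          # consecutive period-k matches
            if match_len < k:               # fewer than two full copies
                continue
            unit = seq[b:b + k]
            if not is_primitive(unit):      # covered by a shorter class
                continue
            repeats = (match_len + k) // k
            length = repeats * k
            if length < config.threshold_for(k):
                continue
            canon = canonical_rotation(unit)
            if canon not in catalog_units:
                continue
            loci.append(SSRLocus(
                seq_id=record.id, motif=canon, repeats=repeats,
                length=length, start=int(b) + 1, end=int(b) + length,
            ))
    loci.sort(key=lambda l: (l.start, l.k))
    return loci


def resolve_overlaps(loci: Sequence[SSRLocus]) -> List[SSRLocus]:
    """Keep only the longer locus among overlapping ones.

    Greedy by (length desc, start asc, motif length asc); survivors are
    pairwise disjoint; output sorted by start.
    """
    ranked = sorted(loci, key=lambda l: (-l.length, l.start, l.k))
    kept: List[SSRLocus] = []
    for cand in ranked:
        if not any(cand.overlaps(other) for other in kept):
            kept.append(cand)
    kept.sort(key=lambda l: l.start)
    return kept


def scan_sequences(
    records: Iterable[SequenceRecord],
    config: Optional[ScanConfig] = None,
    catalog: Optional[Sequence[MotifClass]] = None,
) -> List[SSRLocus]:
    """Scan every record independently; concatenated, overlap-resolved loci.

    When ``catalog`` is omitted it is enumerated from the k values present in
    the config's threshold map (default 1-5).
    """
    if config is None:
        config = ScanConfig()
    if catalog is None:
        ks = config.k_values
        catalog = enumerate_motifs(min(ks), max(ks))
    records = list(records)
    out: List[SSRLocus] = []
    for record in records:
        try:
            raw = find_perfect_runs(record, catalog, config)
            out.extend(resolve_overlaps(raw))
        except Exception as exc:
            raise type(exc)(f"while scanning {record.id!r}: {exc}") from exc
    logger.info("scan: %d locus/loci across %d record(s)", len(out), len(records))
    return out
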