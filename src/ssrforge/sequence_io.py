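"""Multi-FASTA input/output and record validation.

Records are normalized on read: sequences are uppercased, soft-masked
(lowercase) stretches are remembered as per-record intervals, and IUPAC
ambiguity codes other than N are mapped to N with a warning — a perfect
tandem repeat can only ever consist of unambiguous A/C/G/T, so ambiguity
codes can never sit inside a reportable locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Tuple, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from ssrforge.errors import FastaParseError, ValidationError

logger = logging.getLogger(__name__)

_ACGTN = frozenset("ACGTN")
# every other IUPAC nucleotide code collapses to N
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence from a multi-FASTA input.

    Attributes
    ----------
    id : str
        First whitespace-delimited token of the FASTA header.
    description : str
        Remainder of the header line (may be empty).
    seq : str
        Uppercase nucleotide string over {A,C,G,T,N}.
    masked_runs : tuple of (int, int)
        0-based half-open intervals that were lowercase (soft-masked) in the
        input; the bases themselves are stored uppercased in ``seq``.
    """

    id: str
    description: str
    seq: str
    masked_runs: Tuple[Tuple[int, int], ...] = field(default=())

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        bad = set(self.seq) - _ACGTN
        if bad:
            raise ValidationError(
                f"record {self.id!r}: seq contains non-ACGTN characters "
                f"{sorted(bad)} after normalization"
            )


def _lowercase_runs(raw: str) -> Tuple[Tuple[int, int], ...]:
    runs: List[Tuple[int, int]] = []
    start = None
    for i, c in enumerate(raw):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(raw)))
    return tuple(runs)


def normalize_sequence(raw: str, record_id: str = "?") -> Tuple[str, Tuple[Tuple[int, int], ...]]:
    """Uppercase ``raw``, map non-ACGTN IUPAC codes to N, return (seq, mask)."""
    masked = _lowercase_runs(raw)
    seq = raw.upper()
    mapped = seq.translate(_IUPAC_TO_N)
    if mapped != seq:
        n_mapped = sum(a != b for a, b in zip(seq, mapped))
        logger.warning(
            "record %s: mapped %d IUPAC ambiguity base(s) to N", record_id, n_mapped
        )
    return mapped, masked


def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Read a multi-FASTA file into an ordered list of validated records.

    Raises
    ------
    FastaParseError
        Empty file, no ``>`` header, or sequence data before the first header.
    ValidationError
        Duplicate record id or characters that cannot be normalized.
    """
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: sequence data before first '>' header"
            )

    records: List[SequenceRecord] = []
    seen = set()
    with open(path) as handle:
        for header, raw_seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise FastaParseError(f"{path}: record with empty header")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise ValidationError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            seq, masked = normalize_sequence(raw_seq.replace(" ", ""), rec_id)
            records.append(
                SequenceRecord(id=rec_id, description=desc, seq=seq, masked_runs=masked)
            )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    logger.info("read %d sequence(s), %d bp from %s",
                len(records), sum(r.length for r in records), path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path],
                width: int = 60) -> None:
    """Write records as wrapped FASTA; lowercase is restored for masked runs."""
    with open(path, "w") as out:
        for rec in records:
            seq = rec.seq
            if rec.masked_runs:
                chars = list(seq)
                for s, e in rec.masked_runs:
                    chars[s:e] = [c.lower() for c in chars[s:e]]
                seq = "".join(chars)
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
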