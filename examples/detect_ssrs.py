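"""Detect perfect microsatellites in a small multi-FASTA input.

Builds a three-sequence FASTA in a temporary directory, scans it with the
default thresholds (homopolymers > 8 bp; 10/12/12/15 bp minima for 2-5 nt
motifs), and prints one row per detected locus. Note how the interrupted
(CA)n repeat in seq2 is *not* reported — imperfect repeats are discarded —
and how in seq3 the overlapping homopolymer loses to the longer AG repeat.
"""

import tempfile
from pathlib import Path

from ssrforge import read_fasta, scan_sequences

def _seq(*parts: str) -> str:
    return "".join(parts)

FASTA = (
    ">seq1 clean dinucleotide repeat\n"
    + _seq("GGATCGATTACCTGATCGGATA", "ACACACACACAC", "GGATTACGGATCGTTACGGATC")
    + "\n>seq2 interrupted repeat (not reported)\n"
    + _seq("GGATCGATTACCTGATCGGATA", "CACACAGACACA", "GGATTACGGATCGTTACGGATC")
    + "\n>seq3 overlapping homopolymer + dinucleotide\n"
    + _seq("GGATCGATTACCTGATCGGATC", "AAAAAAAAAGAGAGAGAG", "GATTACGGATCGTTACGGAT")
    + "\n"
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "example.fasta"
    path.write_text(FASTA)
    records = read_fasta(path)
    loci = scan_sequences(records)

print(f"{'seq_id':8} {'motif':6} {'repeats':>7} {'length':>6} {'start':>5} {'end':>5}")
for locus in loci:
    print(f"{locus.seq_id:8} {locus.motif:6} {locus.repeats:>7} "
          f"{locus.length:>6} {locus.start:>5} {locus.end:>5}")

print()
print("Each row is one maximal perfect tandem repeat: 'motif' is the")
print("rotation-canonical repeat unit, coordinates are 1-based inclusive.")
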