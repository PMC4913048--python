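"""Design PCR primer pairs around one detected microsatellite.

Plants an (AT)8 repeat in the middle of a 400 bp synthetic read, scans for
it, and designs primers with Primer3-default constraints (18-27 nt,
57-63 degC, 100-300 bp product). The table shows the top-ranked pairs;
lower penalty = closer to the 20 nt / 60 degC / 50% GC optimum.
"""

from ssrforge import (
    PrimerConstraints, design_primer_pairs, generate_background,
    plant_ssrs, scan_sequences,
)
from ssrforge.fixture_generator import PlantSpec

background = generate_background(length=400, gc_target=50.0, seed=8,
                                 forbid_ssrs=True)
record, truth = plant_ssrs(background, [PlantSpec("AT", 8, 193)], seed=8,
                           seq_id="read_1")
(locus,) = scan_sequences([record])
print(f"locus: ({locus.motif})x{locus.repeats} at "
      f"{locus.start}-{locus.end} of a {record.length} bp read\n")

pairs = design_primer_pairs(record, locus, PrimerConstraints())
print(f"{len(pairs)} primer pair(s); best first:\n")
for i, p in enumerate(pairs):
    print(f"pair {i}: product {p.product_size} bp, penalty {p.pair_penalty:.2f}")
    print(f"  left  5'-{p.left.oligo}-3'  "
          f"(pos {p.left.start}, Tm {p.left.tm:.1f} C, GC {p.left.gc_pct:.0f}%)")
    print(f"  right 5'-{p.right.oligo}-3'  "
          f"(pos {p.right.start}, Tm {p.right.tm:.1f} C, GC {p.right.gc_pct:.0f}%)")

print()
print("Both oligos are written 5'->3'; the right primer is the reverse")
print("complement of its genomic window, so the PCR product spans the")
print("full repeat plus both flanks.")
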