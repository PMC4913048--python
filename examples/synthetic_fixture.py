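"""Generate a synthetic test set with a known truth table and verify it.

The generator rejection-samples an SSR-free background at a realistic GC
content (~44.6%, typical of a vertebrate partial-genome survey), plants
perfect and deliberately interrupted repeats at guarded positions, and
returns the exact truth table. Scanning the result recovers precisely the
perfect plants: the truth table and the scan are bijective by construction.
"""

from ssrforge import make_fixture, scan_sequences

records, truths = make_fixture(n_sequences=3, seq_length=1500, seed=42)

perfect = {(t.seq_id, t.motif, t.repeats, t.start, t.end)
           for t in truths if t.kind == "perfect"}
imperfect = [t for t in truths if t.kind == "imperfect"]
found = {(l.seq_id, l.motif, l.repeats, l.start, l.end)
         for l in scan_sequences(records)}

print(f"{len(records)} sequences x {records[0].length} bp")
print(f"planted: {len(perfect)} perfect, {len(imperfect)} interrupted")
print(f"scanner found {len(found)} loci")
print(f"recovered exactly: {found == perfect}")
print(f"missed: {len(perfect - found)}   spurious: {len(found - perfect)}")
print()
print("'recovered exactly: True' means every perfect plant was found at")
print("its exact planted coordinates and none of the interrupted repeats")
print("(imperfect microsatellites) was reported.")
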