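"""Run the complete pipeline: scan, primer design, and all four reports.

Writes the locus TSV, a GFF3 track, Primer3-style Boulder-IO records and a
self-contained HTML report into ./example_output, using a configuration
file that overrides two Primer3 keys, then prints the run summary.
"""

import tempfile
from pathlib import Path

from ssrforge import make_fixture, run_pipeline, write_fasta

CONFIG = """\
# Primer3-style keys port directly
PRIMER_OPT_SIZE=20
PRIMER_PRODUCT_SIZE_RANGE=100-280
# scanner: require 14 bp for dinucleotide repeats
SSR_MIN_LENGTH_2=14
"""

out_dir = Path("example_output")
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    records, _ = make_fixture(n_sequences=4, seq_length=1500, seed=3)
    fasta = tmp / "reads.fasta"
    write_fasta(records, fasta)
    cfg = tmp / "settings.cfg"
    cfg.write_text(CONFIG)
    result = run_pipeline(fasta, config_path=cfg, out_dir=out_dir)

s = result.summary
print(f"sequences      : {s.n_sequences}")
print(f"bp read        : {s.total_bp}")
print(f"GC %           : {s.gc_pct:.2f}")
print(f"SSRs by class  : " + ", ".join(
    f"{k}-mer={v}" for k, v in sorted(s.ssr_counts_by_k.items())))
print(f"SSRs total     : {s.n_ssrs_total}")
print(f"primer pairs   : {s.n_primer_pairs}")
print()
print("outputs:")
for kind, path in result.out_files.items():
    print(f"  {kind:8} {path}")
print()
print("The HTML report lists every locus with its primer pairs (or an")
print("explicit 'no primers' marker for loci whose flanks are unusable).")
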