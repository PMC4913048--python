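# ssrforge

Microsatellite detection and PCR primer design for multi-FASTA nucleotide
sequence sets.

Microsatellites — simple sequence repeats (SSRs), tandem arrays of 1–6 bp
motifs — are workhorse molecular markers in population genetics: they are
highly polymorphic, codominant, and cheap to genotype once locus-specific
PCR primers exist. Mining SSR markers from shotgun or partial-genome
sequencing reads requires two coupled steps: finding perfect repeats long
enough to be useful, and designing primer pairs in the flanking sequence on
both sides of each repeat. `ssrforge` does both in one deterministic,
configurable pipeline, aimed at anyone turning a pile of reads into a
candidate marker panel.

## What it computes

**Detection.** The search space is the set of *primitive*,
*rotation-canonical* repeat units of length k = 1–5 (configurable): a unit
is primitive when it is not a power of a shorter unit (ATAT = AT×2 is
excluded), and canonical when it is the lexicographically smallest of its k
cyclic rotations (AG represents both AG- and GA-phase runs). There are 4,
6, 20, 60 and 204 such classes for k = 1…5. For each class the scanner
reports every *maximal perfect* tandem run — an exact concatenation of ≥ 2
whole copies that cannot be extended — whose total length meets the
per-class minimum (defaults: > 8 bp for homopolymers, i.e. ≥ 9; then
10/12/12/15 bp for k = 2…5). Interrupted ("imperfect") repeats are
deliberately discarded: in lab practice they amplify and score poorly.
When two reported runs overlap, only the longer survives (ties: leftmost,
then shorter motif). Runs never cross an `N`.

**Primer design.** Loci whose flanks cannot physically host two primers
inside the product-size limit are filtered out. For the rest, an exhaustive
engine enumerates every candidate oligo window in each flank, applies
Primer3-default hard constraints (length 18–27 nt, Tm 57–63 °C computed
with the unified SantaLucia nearest-neighbor model, GC 20–80 %, ≤ 5-base
mononucleotide runs, self-complementarity caps), scores candidates by
weighted deviation from the 20 nt / 60 °C / 50 % optima, and ranks pairs by
total penalty under product-size (100–300 bp) and ΔTm (≤ 5 °C) rules. All
parameters are overridable from a flat `KEY=VALUE` file using Primer3 key
names.

**Reporting.** Four artifacts per run: a locus TSV, a GFF3 track
(`microsatellite` features, 1-based), Primer3-native Boulder-IO
`TAG=value` records, and a self-contained static HTML report with run
statistics and per-locus primer tables.

**Synthetic truth sets.** A built-in generator produces FASTA inputs with
planted perfect and interrupted repeats on rejection-sampled, SSR-free
background at a chosen GC content, together with an exact truth table — so
the whole pipeline is testable without downloading anything.

## Worked example

```bash
python examples/detect_ssrs.py
```

```
seq_id   motif  repeats length start   end
seq1     AC           6     12    23    34
seq3     AG           5     10    31    40
```

`seq1` carries a clean (AC)₆ = 12 bp repeat at positions 23–34 (1-based,
inclusive). `seq2` contained the same repeat broken by one substitution —
an imperfect microsatellite — and is absent. `seq3` contained a 9 bp
homopolymer overlapping a 10 bp (AG)₅ run; only the longer AG locus is
reported.

Primer design on a planted (AT)₈ in a 400 bp synthetic read
(`python examples/design_primers.py`) prints, for the top-ranked pair:

```
pair 0: product 147 bp, penalty 3.62
  left  5'-TGATCAGCCAAGCACGGCCC-3'  (pos 115, Tm 59.7 C, GC 65%)
  right 5'-TGTTAGGGTGCTCGGGGCCA-3'  (pos 242, Tm 59.8 C, GC 65%)
```

Both oligos sit wholly in the flanks, so the 147 bp product contains the
complete repeat; the penalty aggregates each oligo's deviation from the
length/Tm/GC optima plus the pair's Tm difference.

The other examples (`synthetic_fixture.py`, `full_report.py`) demonstrate
truth-table generation and the four-file report run. The same pipeline is
available from the shell:

```bash
ssrforge make-fixture --out fx --sequences 4 --length 1500
ssrforge all --input fx/fixture.fasta --out results/
```

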