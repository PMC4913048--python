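# Methods

## Repeat model and detection semantics

A microsatellite locus is modeled as a *perfect* tandem repeat: an exact
concatenation of `repeats ≥ 2` whole copies of a primitive motif of length
k (1–5 by default, hard cap 6). Primitivity excludes motifs that are powers
of shorter ones; rotation-canonicalization (lexicographically smallest
cyclic rotation) gives every physical run a single class name regardless of
the phase at which it begins. Reverse-complement classes are *not* merged:
AG and CT are distinct, so the reported motif always reads directly off the
input strand. Class counts per k are 4, 6, 20, 60, 204 (k = 1…5), the
number of Lyndon-like necklaces of primitive strings over {A,C,G,T}.

The scanner works per motif length k on the periodicity predicate
`s[x] == s[x−k]`: a maximal block of consecutive matches defines a maximal
periodic run, and the reported locus is that run's whole-copy prefix —
`floor(run/k)` copies anchored at the run start. This left-anchored
floor-copy rule is the one deterministic reading under which (i) each
physical run yields exactly one locus, (ii) the locus is always an exact
copy concatenation, and (iii) a partial trailing copy (e.g. the final A of
`ACACACACACA`) extends nothing. Maximality holds in the sense that the base
before the run cannot continue the periodicity and no whole extra copy fits
after the locus. Runs are truncated at `N` (an ambiguity base matches no
motif base; all non-ACGTN IUPAC codes are mapped to N on input, with a
warning, precisely because no perfect repeat can contain them). Soft-masked
(lowercase) regions are scanned by default — shotgun reads are typically
unmasked — and can be excluded with `SSR_SCAN_MASKED=0`.

Implementation: the match array is vectorized with numpy (`a[:-k] == a[k:]`
over the byte view), giving O(n·k_max) per sequence; block extraction via
run-length edges. The brute-force reference used in tests extends copy
counts position by position and checks one-base left-maximality explicitly,
sharing no code with this path.

### Length thresholds

Reported loci must meet a per-class minimum total length:

| k | default minimum (bp) |
|---|---|
| 1 | 9 (homopolymers strictly longer than 8 bp) |
| 2 | 10 |
| 3 | 12 |
| 4 | 12 |
| 5 | 15 |

Only the homopolymer rule is externally fixed; the k ≥ 2 values follow
common SSR-survey practice and are fully overridable
(`SSR_MIN_LENGTH_<k>`). Survey-style counts depend directly on these
values, so they are surfaced prominently rather than buried. Every
threshold must be ≥ 2k (two whole copies).

### Overlap resolution

When reported runs share bases (typical at junctions such as
`AAAAAAAAAGAGAGAGAG`, where a 9 bp A-run and a 10 bp AG-run share one
base), survivors are chosen greedily by length descending, then leftmost
start, then shorter motif; the output is pairwise disjoint. The tie-breaks
are a determinism choice: the shorter motif is the more parsimonious
description of the same stretch. Adjacent runs that merely touch without
sharing a base are both kept — adjacency is not overlap, and compound SSRs
are not merged into one locus.

## Primer engine

The engine is deliberately exhaustive rather than heuristic: every window
of length `size_min..size_max` in the left flank (forward) and right flank
(reverse-complemented) is a candidate. Hard constraints — no N, length,
Tm and GC windows, maximum mononucleotide run, self-complementarity caps —
are binary filters; surviving candidates get a soft penalty

    w_size·|len − size_opt| + w_tm·|Tm − Tm_opt| + w_gc·|GC − GC_opt|

with default weights 1 / 1 / 0.1. Pairs must satisfy product size
(`product_min..product_max`, product = right.end − left.start + 1, always
containing the whole repeat) and |ΔTm| ≤ `max_pair_tm_diff`; pair penalty
is the sum of both candidate penalties plus ΔTm. Ranking is by pair
penalty, then smaller product, then leftmost left primer; at most
`max_pairs_returned` (default 5) pairs are returned. The flank-geometry
pre-filter (`has_sufficient_flanks`) rejects loci whose flanks are shorter
than `size_min` or whose repeat plus two minimum primers exceeds
`product_max` — the dominant loss mode for repeats near read ends.

Enumeration is pruned only by provably-safe geometry (windows from which no
product ≤ `product_max` can exist); tests verify the top-ranked pair
against an unpruned enumerator, so the pruning is an optimization, not an
approximation.

### Melting temperature

Two-state nearest-neighbor model with the unified Allawi–SantaLucia
parameter set: per-stack ΔH/ΔS, terminal A·T (+2.3 kcal/mol, +4.1 eu) and
G·C (+0.1, −2.8) initiation, entropic salt correction
0.368·(N−1)·ln[monovalent] and `Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) −
273.15` for non-self-complementary duplexes. Defaults: 50 mM monovalent
cation, 50 nM total oligo. The model is restricted to oligos ≥ 8 nt
(two-state assumption); divalent/dNTP corrections are out of scope. Tests
require agreement within 0.5 °C with an independent implementation of the
same parameter set (Biopython's `Tm_NN`); in practice the two agree to
machine precision.

### Self-complementarity

Ungapped alignment of the oligo against its own reversed copy at every
offset; each Watson–Crick juxtaposition scores +1, each other
juxtaposition −1, per-offset totals are floored at 0 and maximized.
`self_any` is the maximum over all offsets; `self_end` restricts to
offsets covering the 3′-terminal base (primer-dimer extension risk). A
fully self-complementary palindrome of length n scores n; a homopolymer of
A scores 0. The mismatch term is what makes the Primer3-default caps
(any ≤ 8, 3′-anchored ≤ 3) meaningful as dimer/hairpin filters: without
it, the full-overlap alignment of a random 20-mer already averages five
complementary juxtapositions and every candidate would be rejected.

## Configuration

Flat `KEY=VALUE` text. Primer keys use Primer3 names
(`PRIMER_OPT_SIZE`, `PRIMER_MIN_TM`, `PRIMER_PRODUCT_SIZE_RANGE=lo-hi`,
`PRIMER_NUM_RETURN`, …) so existing Primer3 settings files port directly;
scan keys are `SSR_MIN_LENGTH_<k>`, `SSR_MOTIF_MIN/MAX`,
`SSR_SCAN_MASKED`. Unknown keys are errors (exit 2 from the CLI, naming
the key): silently ignoring a typo in a threshold key would silently change
results.

## Synthetic data generator

The generator emulates the *shape* of single-pass shotgun reads for marker
mining: i.i.d. background nucleotides at a target GC (default 44.65 %, a
typical vertebrate partial-genome value; held within ~3 points for
sequences ≥ 1 kb), with repeats planted at guarded positions (≥ 30 bp from
each other and from the sequence ends). Backgrounds can be
rejection-sampled until the scanner finds nothing in them; planted motif
lengths are drawn uniformly over k so spectra are not dominated by the 204
pentamer classes. Imperfect plants are substitution-interrupted until no
clean sub-run reaches its class threshold (substitution-only is sufficient
to exercise the discard rule; no indels). Two safeguards make the truth
table exact: the single base on each side of a plant is adjusted so the
periodicity cannot leak into the background, and each finished sequence is
verified against the scanner (scan == perfect truth rows, bijectively)
before being accepted, with the whole sequence redrawn otherwise. A single
integer seed (documented default 42) drives all randomness.

What the generator does **not** emulate: sequencing error (including
platform-specific homopolymer miscalls), quality values, read-length
distributions, genomic repeat structure beyond the planted loci, or
compositional heterogeneity along a read. Passing the planted-recovery
tests therefore demonstrates algorithmic correctness of detection and
filtering under the stated model, not robustness to noisy real reads.

## Test and verification scales

The oracle-equivalence suite compares the scanner against the brute-force
enumerator on 1000 random sequences of 200–1000 bp (mixed uniform,
repeat-dense and N-containing compositions); planted-recovery uses 20
sequences × 50 perfect + 5 interrupted plants (5.2 kb each); the primer
engine is checked against unpruned exhaustive enumeration on 100 records
≤ 300 bp; overlap handling on 500 constructed junction strings. The
acceptance script re-runs the same checks at moderately reduced sizes
(e.g. 300 oracle sequences, 40 primer records) chosen to keep a full
reproduction run under a minute while leaving every property
non-trivially exercised.

## Known limitations

* Perfect repeats only — the discard of imperfect microsatellites is a
  modeling decision inherited from lab practice, not a claim that they are
  biologically uninteresting.
* Motifs ≤ 6 nt; no IUPAC/weighted motifs.
* Primer engine omits hairpin ΔG thermodynamics, mispriming libraries,
  internal oligos and multiplex compatibility; it is a transparent,
  testable approximation of the default Primer3 workflow, not a Primer3
  replacement for demanding assay design.
* Per-k thresholds above k = 1 are conventions; comparisons with other SSR
  tools are meaningful only under matched thresholds.
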