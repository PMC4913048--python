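"""Report generation and the end-to-end pipeline.

Three output kinds, mirroring what a bench scientist needs downstream:

* a tab-separated locus table and a GFF3 track (1-based, type
  ``microsatellite``) for programmatic use;
* Boulder-IO ``TAG=value`` records, the Primer3 native format, one
  ``=``-terminated block per locus that entered primer design;
* a single self-contained static HTML report with run statistics, the
  per-class SSR distribution, and each locus with its primer pairs (or an
  explicit "no primers" marker).

Volatile fields (run date, elapsed seconds) are confined to clearly
delimited markers so two runs on the same input are otherwise
byte-identical.
"""

from __future__ import annotations

import html as _html
import io
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

from ssrforge.config import PipelineConfig, load_config
from ssrforge.motif_catalog import enumerate_motifs
from ssrforge.primer_design import PrimerPair, design_primer_pairs, has_sufficient_flanks
from ssrforge.sequence_io import SequenceRecord, read_fasta
from ssrforge.ssr_scanner import SSRLocus, scan_sequences

logger = logging.getLogger(__name__)

SSR_TSV_COLUMNS = ("seq_id", "motif", "k", "repeats", "length", "start", "end")


@dataclass(frozen=True)
class RunSummary:
    """Global statistics of one pipeline run."""

    n_sequences: int
    total_bp: int
    gc_pct: float
    ssr_counts_by_k: Dict[int, int]
    n_ssrs_total: int
    n_primer_pairs: int
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        assert self.n_ssrs_total == sum(self.ssr_counts_by_k.values())
        assert 0.0 <= self.gc_pct <= 100.0 or self.total_bp == 0


def summarize(
    records: Sequence[SequenceRecord],
    loci: Sequence[SSRLocus],
    pairs: Sequence[PrimerPair],
    elapsed: float = 0.0,
) -> RunSummary:
    """Counts by motif-length class plus global GC% (N bases ignored)."""
    total_bp = sum(r.length for r in records)
    acgt = gc = 0
    for r in records:
        for c in r.seq:
            if c in "GC":
                gc += 1
                acgt += 1
            elif c in "AT":
                acgt += 1
    counts: Dict[int, int] = {}
    for locus in loci:
        counts[locus.k] = counts.get(locus.k, 0) + 1
    return RunSummary(
        n_sequences=len(records),
        total_bp=total_bp,
        gc_pct=(100.0 * gc / acgt) if acgt else 0.0,
        ssr_counts_by_k=counts,
        n_ssrs_total=len(loci),
        n_primer_pairs=len(pairs),
        elapsed=elapsed,
    )


# ---------------------------------------------------------------- TSV / GFF3

def write_ssr_tsv(loci: Sequence[SSRLocus], sink: TextIO) -> None:
    sink.write("\t".join(SSR_TSV_COLUMNS) + "\n")
    for l in loci:
        sink.write(f"{l.seq_id}\t{l.motif}\t{l.k}\t{l.repeats}\t"
                   f"{l.length}\t{l.start}\t{l.end}\n")


def write_gff3(loci: Sequence[SSRLocus], sink: TextIO) -> None:
    sink.write("##gff-version 3\n")
    for i, l in enumerate(loci, 1):
        attrs = f"ID=ssr{i:05d};motif={l.motif};repeats={l.repeats}"
        sink.write(f"{l.seq_id}\tssrforge\tmicrosatellite\t{l.start}\t{l.end}"
                   f"\t.\t+\t.\t{attrs}\n")


def read_ssr_tsv(path: Union[str, Path]) -> List[SSRLocus]:
    loci: List[SSRLocus] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        assert tuple(header) == SSR_TSV_COLUMNS, f"unexpected TSV header {header}"
        for line in handle:
            f = line.rstrip("\n").split("\t")
            loci.append(SSRLocus(seq_id=f[0], motif=f[1], repeats=int(f[3]),
                                 length=int(f[4]), start=int(f[5]), end=int(f[6])))
    return loci


# ------------------------------------------------------------- Boulder-IO

def write_primer3_tagvalue(
    record: SequenceRecord,
    locus: SSRLocus,
    pairs: Sequence[PrimerPair],
    sink: Optional[TextIO] = None,
) -> str:
    """One Boulder-IO record for a locus: primer sequences, positions
    (0-based 5' end, Primer3 convention), per-oligo and pair metrics,
    terminated by a lone ``=`` line."""
    buf = io.StringIO()
    buf.write(f"SEQUENCE_ID={record.id}\n")
    buf.write(f"SSRFORGE_TARGET={locus.start},{locus.length}\n")
    buf.write(f"SSRFORGE_MOTIF={locus.motif}\n")
    buf.write(f"PRIMER_PAIR_NUM_RETURNED={len(pairs)}\n")
    for n, pair in enumerate(pairs):
        left, right = pair.left, pair.right
        buf.write(f"PRIMER_LEFT_{n}_SEQUENCE={left.oligo}\n")
        buf.write(f"PRIMER_RIGHT_{n}_SEQUENCE={right.oligo}\n")
        buf.write(f"PRIMER_LEFT_{n}={left.start - 1},{len(left.oligo)}\n")
        buf.write(f"PRIMER_RIGHT_{n}={right.end - 1},{len(right.oligo)}\n")
        buf.write(f"PRIMER_LEFT_{n}_TM={left.tm:.3f}\n")
        buf.write(f"PRIMER_RIGHT_{n}_TM={right.tm:.3f}\n")
        buf.write(f"PRIMER_LEFT_{n}_GC_PERCENT={left.gc_pct:.3f}\n")
        buf.write(f"PRIMER_RIGHT_{n}_GC_PERCENT={right.gc_pct:.3f}\n")
        buf.write(f"PRIMER_LEFT_{n}_PENALTY={left.penalty:.4f}\n")
        buf.write(f"PRIMER_RIGHT_{n}_PENALTY={right.penalty:.4f}\n")
        buf.write(f"PRIMER_PAIR_{n}_PENALTY={pair.pair_penalty:.4f}\n")
        buf.write(f"PRIMER_PAIR_{n}_PRODUCT_SIZE={pair.product_size}\n")
    buf.write("=\n")
    text = buf.getvalue()
    if sink is not None:
        sink.write(text)
    return text


def parse_boulder(text: str) -> List[Dict[str, str]]:
    """Parse ``TAG=value`` records separated by lone ``=`` lines."""
    blocks: List[Dict[str, str]] = []
    current: Dict[str, str] = {}
    for line in text.splitlines():
        if line == "=":
            blocks.append(current)
            current = {}
        elif line:
            tag, _, value = line.partition("=")
            current[tag] = value
    return blocks


# ------------------------------------------------------------------- HTML

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head><meta charset="utf-8"><title>ssrforge report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.8em; }}
.nopairs {{ color: #a00; }}
</style></head>
<body>
<h1>Microsatellite survey report</h1>
<p>Run date: <!--VOLATILE-->{run_date}<!--/VOLATILE--> &middot;
elapsed: <!--VOLATILE-->{elapsed:.2f}<!--/VOLATILE--> s</p>
<h2>Summary</h2>
<table id="summary">
<tr><th>Sequences</th><td>{n_sequences}</td></tr>
<tr><th>Base pairs read</th><td>{total_bp}</td></tr>
<tr><th>GC %</th><td>{gc_pct:.2f}</td></tr>
<tr><th>SSRs found</th><td>{n_ssrs}</td></tr>
<tr><th>Primer pairs designed</th><td>{n_pairs}</td></tr>
</table>
<h2>SSR distribution by motif length</h2>
<table id="distribution">
<tr><th>Class</th><th>Count</th></tr>
{dist_rows}
<tr><th>Total</th><th>{n_ssrs}</th></tr>
</table>
<h2>Loci and primers</h2>
{locus_sections}
</body>
</html>
"""


def render_html(
    summary: RunSummary,
    loci: Sequence[SSRLocus],
    pairs_by_locus: Dict[Tuple[str, int, int], List[PrimerPair]],
) -> str:
    """A single self-contained static page; no scripts, no external assets."""
    esc = _html.escape
    dist_rows = "\n".join(
        f"<tr><td>{k}-mer</td><td>{summary.ssr_counts_by_k.get(k, 0)}</td></tr>"
        for k in sorted(summary.ssr_counts_by_k) or range(0)
    )
    sections: List[str] = []
    for locus in loci:
        key = (locus.seq_id, locus.start, locus.end)
        pairs = pairs_by_locus.get(key, [])
        head = (f"<h3>{esc(locus.seq_id)} : ({esc(locus.motif)})"
                f"<sub>{locus.repeats}</sub> at {locus.start}&ndash;{locus.end}"
                f" ({locus.length} bp)</h3>")
        if not pairs:
            sections.append(
                head + '<p class="nopairs">no primers</p>')
            continue
        rows = []
        for n, p in enumerate(pairs):
            rows.append(
                f"<tr><td>{n}</td>"
                f"<td>{esc(p.left.oligo)}</td><td>{p.left.tm:.1f}</td>"
                f"<td>{p.left.gc_pct:.1f}</td>"
                f"<td>{esc(p.right.oligo)}</td><td>{p.right.tm:.1f}</td>"
                f"<td>{p.right.gc_pct:.1f}</td>"
                f"<td>{p.product_size}</td><td>{p.pair_penalty:.2f}</td></tr>"
            )
        sections.append(
            head
            + '<table><tr><th>#</th><th>Left primer 5&rsquo;&rarr;3&rsquo;</th>'
              "<th>Tm</th><th>GC%</th>"
              '<th>Right primer 5&rsquo;&rarr;3&rsquo;</th><th>Tm</th>'
              "<th>GC%</th><th>Product</th><th>Penalty</th></tr>"
            + "\n".join(rows) + "</table>"
        )
    return _PAGE.format(
        run_date=time.strftime("%Y-%m-%d %H:%M:%S"),
        elapsed=summary.elapsed,
        n_sequences=summary.n_sequences,
        total_bp=summary.total_bp,
        gc_pct=summary.gc_pct,
        n_ssrs=summary.n_ssrs_total,
        n_pairs=summary.n_primer_pairs,
        dist_rows=dist_rows,
        locus_sections="\n".join(sections) if sections
        else "<p>No microsatellites found.</p>",
    )


# ---------------------------------------------------------------- pipeline

@dataclass(frozen=True)
class PipelineResult:
    """Everything one run produced, with the paths that were written."""

    records: List[SequenceRecord]
    loci: List[SSRLocus]
    pairs_by_locus: Dict[Tuple[str, int, int], List[PrimerPair]]
    summary: RunSummary
    out_files: Dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    input_fasta: Union[str, Path],
    config_path: Union[str, Path, None] = None,
    out_dir: Union[str, Path, None] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Scan, design, and report: the full run over one multi-FASTA input.

    Writes ``ssr_table.tsv``, ``ssr_loci.gff3``, ``primers.boulder`` and
    ``report.html`` into ``out_dir`` (when given). Outputs are deterministic
    for a fixed input and configuration, apart from the delimited run-date /
    elapsed fields in the HTML.
    """
    t0 = time.monotonic()
    if config is None:
        config = load_config(config_path)
    records = read_fasta(input_fasta)
    catalog = enumerate_motifs(config.motif_min, config.motif_max)
    loci = scan_sequences(records, config.scan, catalog)
    logger.info("found %d SSR locus/loci", len(loci))

    by_id = {r.id: r for r in records}
    pairs_by_locus: Dict[Tuple[str, int, int], List[PrimerPair]] = {}
    all_pairs: List[PrimerPair] = []
    n_designable = 0
    for locus in loci:
        record = by_id[locus.seq_id]
        key = (locus.seq_id, locus.start, locus.end)
        if not has_sufficient_flanks(locus, record.length, config.primers):
            pairs_by_locus[key] = []
            continue
        n_designable += 1
        pairs = design_primer_pairs(record, locus, config.primers)
        pairs_by_locus[key] = pairs
        all_pairs.extend(pairs)
    logger.info("%d locus/loci with usable flanks; %d primer pair(s) designed",
                n_designable, len(all_pairs))

    summary = summarize(records, loci, all_pairs,
                        elapsed=time.monotonic() - t0)

    out_files: Dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tsv = out_dir / "ssr_table.tsv"
        with open(tsv, "w") as sink:
            write_ssr_tsv(loci, sink)
        gff = out_dir / "ssr_loci.gff3"
        with open(gff, "w") as sink:
            write_gff3(loci, sink)
        boulder = out_dir / "primers.boulder"
        with open(boulder, "w") as sink:
            for locus in loci:
                key = (locus.seq_id, locus.start, locus.end)
                record = by_id[locus.seq_id]
                write_primer3_tagvalue(record, locus,
                                       pairs_by_locus[key], sink)
        report = out_dir / "report.html"
        report.write_text(render_html(summary, loci, pairs_by_locus))
        out_files = {"tsv": tsv, "gff3": gff, "boulder": boulder,
                     "html": report}

    return PipelineResult(records=records, loci=loci,
                          pairs_by_locus=pairs_by_locus,
                          summary=summary, out_files=out_files)
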