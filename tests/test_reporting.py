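import re
from html.parser import HTMLParser

import pytest
from click.testing import CliRunner

from ssrforge.cli import main as cli_main
from ssrforge.fixture_generator import make_fixture
from ssrforge.primer_design import design_primer_pairs
from ssrforge.reporting import (
    parse_boulder, read_ssr_tsv, render_html, run_pipeline, summarize,
    write_primer3_tagvalue,
)
from ssrforge.sequence_io import SequenceRecord, write_fasta
from ssrforge.ssr_scanner import scan_sequences


@pytest.fixture(scope="module")
def fixture_run(tmp_path_factory):
    d = tmp_path_factory.mktemp("run")
    records, truths = make_fixture(n_sequences=3, seq_length=1200, seed=13)
    fasta = d / "in.fasta"
    write_fasta(records, fasta)
    result = run_pipeline(fasta, out_dir=d / "out")
    return d, fasta, result


class TestSummarize:
    def test_empty_run(self):
        s = summarize([], [], [])
        assert (s.n_sequences, s.total_bp, s.n_ssrs_total,
                s.n_primer_pairs) == (0, 0, 0, 0)

    def test_single_dimer_record(self):
        rec = SequenceRecord(id="r", description="", seq="ACACACACAC")
        loci = scan_sequences([rec])
        s = summarize([rec], loci, [])
        assert (s.n_sequences, s.total_bp) == (1, 10)
        assert s.gc_pct == pytest.approx(50.0)
        assert s.ssr_counts_by_k == {2: 1}
        assert s.n_ssrs_total == 1

    def test_gc_ignores_n(self):
        rec = SequenceRecord(id="r", description="", seq="GGNNNN")
        assert summarize([rec], [], []).gc_pct == pytest.approx(100.0)

    def test_counts_match_fixture_truth(self):
        records, truths = make_fixture(n_sequences=2, seq_length=1200, seed=17)
        loci = scan_sequences(records)
        s = summarize(records, loci, [])
        expected = {}
        for t in truths:
            if t.kind == "perfect":
                k = len(t.motif)
                expected[k] = expected.get(k, 0) + 1
        assert s.ssr_counts_by_k == expected


class TestBoulderIO:
    def make_locus_with_pairs(self):
        records, _ = make_fixture(n_sequences=1, seq_length=1200, seed=19)
        rec = records[0]
        loci = scan_sequences(records)
        for locus in loci:
            pairs = design_primer_pairs(rec, locus)
            if pairs:
                return rec, locus, pairs
        pytest.fail("fixture yielded no designable locus")

    def test_zero_pairs_block(self):
        rec = SequenceRecord(id="r", description="", seq="ACGT" * 10)
        from ssrforge.ssr_scanner import SSRLocus
        locus = SSRLocus("r", "AC", 5, 10, 16, 25)
        text = write_primer3_tagvalue(rec, locus, [])
        assert text.endswith("=\n")
        (block,) = parse_boulder(text)
        assert block["SEQUENCE_ID"] == "r"
        assert block["PRIMER_PAIR_NUM_RETURNED"] == "0"

    def test_round_trip_preserves_oligos_and_positions(self):
        rec, locus, pairs = self.make_locus_with_pairs()
        (block,) = parse_boulder(write_primer3_tagvalue(rec, locus, pairs))
        assert int(block["PRIMER_PAIR_NUM_RETURNED"]) == len(pairs)
        for n, p in enumerate(pairs):
            assert block[f"PRIMER_LEFT_{n}_SEQUENCE"] == p.left.oligo
            assert block[f"PRIMER_RIGHT_{n}_SEQUENCE"] == p.right.oligo
            pos, length = map(int, block[f"PRIMER_LEFT_{n}"].split(","))
            assert (pos, length) == (p.left.start - 1, len(p.left.oligo))
            assert int(block[f"PRIMER_PAIR_{n}_PRODUCT_SIZE"]) == p.product_size


class _Validator(HTMLParser):
    def __init__(self):
        super().__init__()
        self.tags = []

    def handle_starttag(self, tag, attrs):
        self.tags.append(tag)


class TestHTML:
    def test_empty_run_is_valid_page(self):
        page = render_html(summarize([], [], []), [], {})
        v = _Validator()
        v.feed(page)
        assert "table" in v.tags
        assert "No microsatellites found" in page

    def test_page_contains_motifs_and_oligos(self, fixture_run):
        _, _, result = fixture_run
        page = (result.out_files["html"]).read_text()
        v = _Validator()
        v.feed(page)  # parses without error
        for locus in result.loci:
            assert locus.motif in page
        for pairs in result.pairs_by_locus.values():
            for p in pairs:
                assert p.left.oligo in page and p.right.oligo in page
        n_sections = page.count("<h3>")
        assert n_sections == len(result.loci)


def mask_volatile(text):
    return re.sub(r"<!--VOLATILE-->.*?<!--/VOLATILE-->", "#", text,
                  flags=re.S)


class TestPipeline:
    def test_outputs_exist_and_nonempty(self, fixture_run):
        _, _, result = fixture_run
        assert set(result.out_files) == {"tsv", "gff3", "boulder", "html"}
        for p in result.out_files.values():
            assert p.stat().st_size > 0

    def test_cross_format_locus_consistency(self, fixture_run):
        _, _, result = fixture_run
        expected = {(l.seq_id, l.start, l.end, l.motif) for l in result.loci}
        tsv = {(l.seq_id, l.start, l.end, l.motif)
               for l in read_ssr_tsv(result.out_files["tsv"])}
        assert tsv == expected
        gff = set()
        for line in result.out_files["gff3"].read_text().splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            motif = dict(kv.split("=") for kv in f[8].split(";"))["motif"]
            gff.add((f[0], int(f[3]), int(f[4]), motif))
        assert gff == expected
        boulder = parse_boulder(result.out_files["boulder"].read_text())
        b_keys = {(b["SEQUENCE_ID"],
                   int(b["SSRFORGE_TARGET"].split(",")[0]),
                   b["SSRFORGE_MOTIF"]) for b in boulder}
        assert b_keys == {(sid, start, m) for sid, start, _, m in expected}

    def test_two_runs_identical_modulo_timestamps(self, fixture_run, tmp_path):
        d, fasta, result = fixture_run
        again = run_pipeline(fasta, out_dir=tmp_path / "out2")
        for key in ("tsv", "gff3", "boulder"):
            assert result.out_files[key].read_text() == \
                again.out_files[key].read_text()
        assert mask_volatile(result.out_files["html"].read_text()) == \
            mask_volatile(again.out_files["html"].read_text())


class TestCLI:
    def test_missing_input_exits_2(self, tmp_path):
        r = CliRunner().invoke(
            cli_main, ["scan", "--input", str(tmp_path / "nope.fasta")])
        assert r.exit_code == 2

    def test_bad_config_key_exits_2(self, fixture_run, tmp_path):
        _, fasta, _ = fixture_run
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("PRIMER_BOGUS_KEY=1\n")
        r = CliRunner().invoke(
            cli_main, ["all", "--input", str(fasta), "--config", str(cfg),
                       "--out", str(tmp_path / "o")])
        assert r.exit_code == 2
        assert "PRIMER_BOGUS_KEY" in r.output

    def test_full_run_exit_0(self, fixture_run, tmp_path):
        _, fasta, _ = fixture_run
        out = tmp_path / "cli_out"
        r = CliRunner().invoke(
            cli_main, ["all", "--input", str(fasta), "--out", str(out)])
        assert r.exit_code == 0
        assert (out / "report.html").exists()

    def test_make_fixture_command(self, tmp_path):
        out = tmp_path / "fx"
        r = CliRunner().invoke(
            cli_main, ["make-fixture", "--out", str(out),
                       "--sequences", "1", "--length", "600"])
        assert r.exit_code == 0
        assert (out / "fixture.fasta").exists()
        assert (out / "truth.tsv").exists()
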